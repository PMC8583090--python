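"""Reversal scoring of drug perturbation profiles against a disease signature.

A perturbation profile ranks genes most-upregulated first.  Each of the
signature's up-set U and down-set D gets a connectivity-map style KS
enrichment score: with sorted 1-based hit positions p_1 < ... < p_s in a
universe of N genes,

    a = max_j (j/s - p_j/N),   b = max_j (p_j/N - (j-1)/s),
    ES = a if a >= b else -b.

RGES = ES_up - ES_down when the two scores have opposite signs (or either is
zero) and 0 otherwise; negative RGES means the drug pushes the up-set down
and the down-set up, i.e. reverses the disease signature.  Per-drug sRGES is
a similarity-weighted mean of RGES after shifting non-reference dose/time
profiles toward the reference condition (10 uM, 24 h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import DiseaseSignature

REFERENCE_DOSE_UM = 10.0
REFERENCE_TIME_H = 24.0
SRGES_CUTOFF = -0.25
MIN_STRONG_PROFILES = 3


@dataclass
class PerturbationProfile:
    """One drug x cell line x dose x time differential-expression ranking."""

    drug: str
    cell_line: str
    dose: float
    time: float
    ranking: tuple  # gene labels, most up-regulated first

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.time <= 0:
            raise ValueError("time must be positive")
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError("ranking contains duplicate genes")

    @property
    def n_genes(self) -> int:
        return len(self.ranking)


class PerturbationLibrary:
    """Profiles stored as a meta table plus a profiles x genes value matrix."""

    def __init__(self, meta: pd.DataFrame, values: np.ndarray, genes: Sequence[str]):
        meta = meta.reset_index(drop=True)
        required = {"drug", "cell_line", "dose_uM", "time_h"}
        if missing := required - set(meta.columns):
            raise ValueError(f"meta table missing columns: {sorted(missing)}")
        if values.shape != (len(meta), len(genes)):
            raise ValueError("values shape does not match meta/genes")
        self.meta = meta
        self.values = np.asarray(values, dtype=float)
        self.genes = list(genes)

    def __len__(self) -> int:
        return len(self.meta)

    def profile(self, i: int) -> PerturbationProfile:
        order = np.argsort(-self.values[i], kind="stable")
        row = self.meta.iloc[i]
        return PerturbationProfile(
            drug=row["drug"],
            cell_line=row["cell_line"],
            dose=float(row["dose_uM"]),
            time=float(row["time_h"]),
            ranking=tuple(self.genes[j] for j in order),
        )

    def to_long(self) -> pd.DataFrame:
        n_p, n_g = self.values.shape
        return pd.DataFrame(
            {
                "drug": np.repeat(self.meta["drug"].to_numpy(), n_g),
                "cell_line": np.repeat(self.meta["cell_line"].to_numpy(), n_g),
                "dose_uM": np.repeat(self.meta["dose_uM"].to_numpy(), n_g),
                "time_h": np.repeat(self.meta["time_h"].to_numpy(), n_g),
                "gene": np.tile(np.asarray(self.genes, dtype=object), n_p),
                "value": self.values.ravel(),
            }
        )

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "PerturbationLibrary":
        keys = ["drug", "cell_line", "dose_uM", "time_h"]
        wide = long.pivot_table(index=keys, columns="gene", values="value", sort=False)
        meta = wide.index.to_frame(index=False)
        return cls(meta=meta, values=wide.to_numpy(), genes=list(wide.columns))


def _ks_from_positions(positions: np.ndarray, n_genes: int) -> float:
    pos = np.sort(np.asarray(positions, dtype=float))
    s = pos.size
    j = np.arange(1, s + 1, dtype=float)
    a = np.max(j / s - pos / n_genes)
    b = np.max(pos / n_genes - (j - 1) / s)
    return float(a) if a >= b else float(-b)


def enrichment_score(set_s: frozenset | set, profile: PerturbationProfile) -> float:
    """KS enrichment of gene set S in the profile's ranking, in [-1, 1]."""
    universe = profile.ranking
    hits = set(set_s) & set(universe)
    if not hits:
        raise ValueError(
            f"gene set has empty intersection with profile universe "
            f"(drug={profile.drug!r}, cell_line={profile.cell_line!r})"
        )
    if len(hits) >= len(universe):
        raise ValueError("gene set must be a proper subset of the profile universe")
    index = {g: i + 1 for i, g in enumerate(universe)}  # 1-based ranks
    positions = np.array([index[g] for g in hits])
    return _ks_from_positions(positions, len(universe))


def _rges_from_scores(es_up: float, es_down: float) -> float:
    if es_up * es_down > 0:
        return 0.0
    return es_up - es_down


def compute_rges(sig: DiseaseSignature, profile: PerturbationProfile) -> dict:
    """RGES of one profile against one signature; negative = reversal."""
    es_up = enrichment_score(sig.up, profile)
    es_down = enrichment_score(sig.down, profile)
    return {
        "drug": profile.drug,
        "cell_line": profile.cell_line,
        "dose_uM": profile.dose,
        "time_h": profile.time,
        "es_up": es_up,
        "es_down": es_down,
        "rges": _rges_from_scores(es_up, es_down),
    }


def score_library(sig: DiseaseSignature, library: PerturbationLibrary) -> pd.DataFrame:
    """Vectorized RGES of every profile in the library against a signature.

    Equivalent to calling :func:`compute_rges` per profile but ranks all
    profiles in one pass.
    """
    gene_index = {g: i for i, g in enumerate(library.genes)}
    up_idx = np.array(sorted(gene_index[g] for g in sig.up if g in gene_index))
    down_idx = np.array(sorted(gene_index[g] for g in sig.down if g in gene_index))
    if up_idx.size == 0 or down_idx.size == 0:
        raise ValueError(
            f"signature {sig.dataset_id!r} has no up or no down genes in the "
            "library universe"
        )
    n = len(library.genes)
    order = np.argsort(-library.values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(order.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]

    def _es_block(idx: np.ndarray) -> np.ndarray:
        pos = np.sort(ranks[:, idx], axis=1).astype(float)
        s = idx.size
        j = np.arange(1, s + 1, dtype=float)[None, :]
        a = np.max(j / s - pos / n, axis=1)
        b = np.max(pos / n - (j - 1) / s, axis=1)
        return np.where(a >= b, a, -b)

    es_up = _es_block(up_idx)
    es_down = _es_block(down_idx)
    rges = np.where(es_up * es_down > 0, 0.0, es_up - es_down)
    out = library.meta.copy()
    out["es_up"] = es_up
    out["es_down"] = es_down
    out["rges"] = rges
    out["signature"] = sig.dataset_id
    return out


def estimate_dose_time_offsets(records: pd.DataFrame) -> tuple[float, float]:
    """Median per-drug RGES shift of non-reference dose/time vs reference.

    Returns (alpha, beta): alpha for dose < 10 uM, beta for time < 24 h.
    Degenerate inputs (no drug observed at both conditions) yield 0 with a
    warning.
    """
    ref = (records["dose_uM"] >= REFERENCE_DOSE_UM) & (records["time_h"] >= REFERENCE_TIME_H)

    def _offset(nonref_mask: pd.Series, label: str) -> float:
        diffs = []
        for _, grp in records.groupby("drug", sort=True):
            ref_grp = grp[ref.loc[grp.index]]
            non_grp = grp[nonref_mask.loc[grp.index]]
            if len(ref_grp) and len(non_grp):
                diffs.append(non_grp["rges"].mean() - ref_grp["rges"].mean())
        if not diffs:
            warnings.warn(
                f"no drug observed at both reference and non-reference {label}; "
                "offset set to 0",
                stacklevel=3,
            )
            return 0.0
        return float(np.median(diffs))

    low_dose = (records["dose_uM"] < REFERENCE_DOSE_UM) & (records["time_h"] >= REFERENCE_TIME_H)
    short_time = (records["time_h"] < REFERENCE_TIME_H) & (records["dose_uM"] >= REFERENCE_DOSE_UM)
    return _offset(low_dose, "dose"), _offset(short_time, "time")


def summarize_srges(
    records: pd.DataFrame,
    similarity: Mapping[str, float] | None = None,
    offsets: tuple[float, float] = (0.0, 0.0),
    strong_cutoff: float = SRGES_CUTOFF,
) -> pd.DataFrame:
    """Per-drug summarized RGES (sRGES) with support counts.

    Profiles at non-reference dose/time are shifted by the supplied offsets;
    cell lines are weighted by tumor similarity (missing lines get weight 1,
    negative similarities are clipped to 0).  n_strong counts raw per-profile
    RGES below the cutoff.
    """
    similarity = dict(similarity or {})
    alpha, beta = offsets
    rec = records.copy()
    rec["adj_rges"] = (
        rec["rges"]
        - alpha * (rec["dose_uM"] < REFERENCE_DOSE_UM)
        - beta * (rec["time_h"] < REFERENCE_TIME_H)
    )
    rec["weight"] = [max(float(similarity.get(cl, 1.0)), 0.0) for cl in rec["cell_line"]]

    rows = []
    for drug, grp in rec.groupby("drug", sort=True):
        w = grp["weight"].to_numpy()
        if w.sum() == 0:
            warnings.warn(f"all similarity weights zero for drug {drug!r}; using uniform", stacklevel=2)
            w = np.ones_like(w)
        w = w / w.sum()
        rows.append(
            {
                "drug": drug,
                "srges": float(np.dot(w, grp["adj_rges"].to_numpy())),
                "n_profiles": len(grp),
                "n_strong": int((grp["rges"] < strong_cutoff).sum()),
            }
        )
    return pd.DataFrame(rows)


def select_candidates(
    srges_table: pd.DataFrame,
    top_n: int = 100,
    srges_cut: float = SRGES_CUTOFF,
    min_strong: int = MIN_STRONG_PROFILES,
) -> pd.DataFrame:
    """Apply the candidate rule: sRGES < cutoff AND strong support in > 2 profiles.

    Tables from multiple signatures may be concatenated; a drug qualifying in
    several signatures is kept once at its lowest sRGES.  The surviving drugs
    are sorted ascending by sRGES, ranked, and truncated to top_n.
    """
    if srges_table.empty:
        raise ValueError("empty sRGES table")
    keep = srges_table[(srges_table["srges"] < srges_cut) & (srges_table["n_strong"] >= min_strong)]
    keep = keep.sort_values(["srges", "drug"], kind="mergesort")
    keep = keep.loc[~keep["drug"].duplicated(keep="first")]
    keep = keep.head(top_n).reset_index(drop=True)
    keep.insert(1, "rank", np.arange(1, len(keep) + 1))
    return keep


def aggregate_moa(
    candidates: pd.DataFrame,
    annotations: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Count candidates per mechanism of action and per shared target gene.

    annotations: DataFrame indexed by drug with columns moa, targets (iterable
    or ';'-joined string), clinical_phase.  Unannotated drugs count as
    "unknown"; targets are reported only when shared by >= 2 candidate drugs.
    """
    moa_counts: dict[str, int] = {}
    target_counts: dict[str, int] = {}
    for drug in candidates["drug"]:
        if drug in annotations.index:
            row = annotations.loc[drug]
            moa = row.get("moa", "unknown") or "unknown"
            targets = row.get("targets", ())
            if isinstance(targets, str):
                targets = [t for t in targets.split(";") if t]
        else:
            moa, targets = "unknown", ()
        moa_counts[moa] = moa_counts.get(moa, 0) + 1
        for t in targets:
            target_counts[t] = target_counts.get(t, 0) + 1
    moa_series = pd.Series(moa_counts, name="n_drugs").sort_values(ascending=False)
    shared = {t: c for t, c in target_counts.items() if c >= 2}
    target_series = pd.Series(shared, name="n_drugs", dtype=int).sort_values(ascending=False)
    return moa_series, target_series
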