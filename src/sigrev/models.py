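"""Model cell-line selection, drug sensitivity and biomarker genomics.

Covers: transcriptional similarity of cell lines to a disease signature,
dose-response sensitivity summaries (normalized AUC over log10 dose and a
low-dose score), Pearson correlation of copy number / expression features
with sensitivity, copy-number segment filtering with the probe-count and
length thresholds used for CytoScan-style calls, gene-level GISTIC-style
categorization, and a decile-based dependency efficacy/selectivity summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ConsensusList
from .signatures import DiseaseSignature

# segment retention thresholds (probe counts / bp)
MIN_PROBES_LOSS = 25
MIN_PROBES_GAIN = 50
MIN_CNLOH_BP = 5_000_000

#: GISTIC-style category bounds on x = log2(copy ratio relative to ploidy + 1);
#: neutral (at ploidy) encodes to exactly 1.0.
GISTIC_BOUNDS = (0.3, 0.8, 1.2, 1.55)


@dataclass
class CellLineProfile:
    """Per-line expression log2(TPM+1) and copy number log2(rel-to-ploidy+1)."""

    cell_line: str
    expression: pd.Series
    cn: pd.Series
    lineage: str = ""

    def __post_init__(self) -> None:
        if (self.expression < 0).any():
            raise ValueError(f"negative expression values for {self.cell_line!r}")


@dataclass
class DoseResponseCurve:
    drug: str
    cell_line: str
    points: pd.DataFrame  # columns: dose_uM, viability_log2fc

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("need at least 2 dose points")
        doses = self.points["dose_uM"]
        if (doses <= 0).any():
            raise ValueError("doses must be positive")
        if doses.duplicated().any():
            raise ValueError(f"duplicate doses for {self.drug}/{self.cell_line}")


def cellline_similarity(
    sig: DiseaseSignature,
    lines: Sequence[CellLineProfile],
) -> pd.Series:
    """Spearman similarity of each line's differential profile to the signature.

    The line differential is its expression minus the per-gene median across
    all supplied lines, restricted to the signature's U∪D genes.  Lines with
    fewer than 10 overlapping genes are skipped with a warning.
    """
    sig_genes = sorted(sig.genes)
    expr = pd.DataFrame({ln.cell_line: ln.expression for ln in lines})
    median = expr.median(axis=1)
    lfc = sig.log2fc(sig_genes)

    scores = {}
    for ln in lines:
        diff = (ln.expression - median).reindex(sig_genes)
        ok = diff.notna() & lfc.notna()
        if ok.sum() < 10:
            warnings.warn(
                f"cell line {ln.cell_line!r} shares <10 signature genes; skipped",
                stacklevel=2,
            )
            continue
        rho = stats.spearmanr(diff[ok], lfc[ok]).statistic
        scores[ln.cell_line] = float(rho)
    return pd.Series(scores, name="similarity").sort_values(ascending=False, kind="mergesort")


def select_model_lines(
    similarities: pd.Series,
    consensus: ConsensusList | Sequence[str],
    k: int,
) -> list[str]:
    """Intersect the top-k most similar lines with the consensus list.

    Falls back to plain top-k similarity (with a warning) when the
    intersection has fewer than 3 lines.
    """
    if similarities.empty:
        raise ValueError("empty similarity table")
    consensus_lines = (
        set(consensus.included_terms) if isinstance(consensus, ConsensusList) else set(consensus)
    )
    ranked = similarities.sort_values(ascending=False, kind="mergesort")
    top_k = list(ranked.index[:k])
    chosen = [ln for ln in top_k if ln in consensus_lines]
    if len(chosen) < 3:
        warnings.warn(
            "fewer than 3 lines in the consensus/top-k intersection; "
            "falling back to top-k similarity",
            stacklevel=2,
        )
        return top_k
    return chosen


def dose_response_metrics(curve: DoseResponseCurve, n_low: int = 3) -> dict:
    """Normalized AUC over log10 dose plus a low-dose sensitivity score.

    AUC is the trapezoid of viability log2FC over log10 dose divided by the
    log10-dose span, so a flat curve at value v has AUC exactly v.  The
    low-dose score is the mean viability at the n_low smallest doses.
    """
    pts = curve.points.sort_values("dose_uM", kind="mergesort")
    log_dose = np.log10(pts["dose_uM"].to_numpy(dtype=float))
    v = pts["viability_log2fc"].to_numpy(dtype=float)
    span = log_dose[-1] - log_dose[0]
    auc = float(np.trapezoid(v, log_dose) / span)
    n_low = max(1, min(n_low, len(v)))
    return {
        "drug": curve.drug,
        "cell_line": curve.cell_line,
        "auc": auc,
        "low_dose_score": float(v[:n_low].mean()),
    }


def sensitivity_table(curves: Sequence[DoseResponseCurve], n_low: int = 3) -> pd.DataFrame:
    return pd.DataFrame([dose_response_metrics(c, n_low=n_low) for c in curves])


def biomarker_correlation(
    metrics: pd.DataFrame,
    lines: Sequence[CellLineProfile],
    genes: Sequence[str],
    metric_col: str = "auc",
) -> pd.DataFrame:
    """Pearson r of gene CN/expression vs drug sensitivity across lines.

    One row per (gene, modality, drug) with r, two-sided t-based p and the
    sample count; zero-variance features are flagged with r = NaN.
    """
    profile_by_line = {ln.cell_line: ln for ln in lines}
    rows = []
    for drug, grp in metrics.groupby("drug", sort=True):
        grp = grp[grp["cell_line"].isin(profile_by_line)]
        if len(grp) < 3:
            raise ValueError(f"fewer than 3 lines shared with profiles for drug {drug!r}")
        sens = grp.set_index("cell_line")[metric_col]
        for gene in genes:
            for modality in ("cn", "expression"):
                feat = pd.Series(
                    {
                        cl: getattr(profile_by_line[cl], modality).get(gene, np.nan)
                        for cl in sens.index
                    }
                )
                ok = feat.notna()
                x, y = feat[ok].to_numpy(), sens[ok].to_numpy()
                flagged = len(x) < 3 or np.std(x) == 0 or np.std(y) == 0
                if flagged:
                    r, p = np.nan, np.nan
                else:
                    res = stats.pearsonr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
                rows.append(
                    {
                        "gene": gene,
                        "modality": modality,
                        "drug": drug,
                        "r": r,
                        "p": p,
                        "n": int(ok.sum()),
                        "zero_variance": flagged,
                    }
                )
    return pd.DataFrame(rows)


def filter_cn_segments(
    segments: pd.DataFrame,
    min_probes_loss: int = MIN_PROBES_LOSS,
    min_probes_gain: int = MIN_PROBES_GAIN,
    min_cnloh_bp: int = MIN_CNLOH_BP,
) -> pd.DataFrame:
    """Retain segments passing the per-type evidence thresholds.

    loss: probe_count >= 25; gain: probe_count >= 50; cnLOH: length >= 5 Mb.
    Unknown types are dropped and counted in ``attrs['n_rejected_type']``;
    per-type retained counts are in ``attrs['retained_counts']``.
    """
    if (segments["end"] <= segments["start"]).any():
        raise ValueError("segments must satisfy end > start")
    known = segments["type"].isin(["gain", "loss", "cnLOH"])
    n_bad = int((~known).sum())
    seg = segments[known]
    length = seg["end"] - seg["start"]
    keep = (
        ((seg["type"] == "loss") & (seg["probe_count"] >= min_probes_loss))
        | ((seg["type"] == "gain") & (seg["probe_count"] >= min_probes_gain))
        | ((seg["type"] == "cnLOH") & (length >= min_cnloh_bp))
    )
    out = seg[keep].reset_index(drop=True)
    out.attrs["n_rejected_type"] = n_bad
    out.attrs["retained_counts"] = out["type"].value_counts().to_dict()
    return out


def gene_level_cn_summary(
    retained: pd.DataFrame,
    gene_coords: Mapping[str, tuple],
    samples: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample gene state from maximal segment overlap, plus frequencies.

    gene_coords maps gene -> (chromosome, start, end), 0-based half-open on
    the same assembly as the segments.  A gene with no overlapping retained
    segment is neutral; equal-overlap contradictory segments also yield
    neutral with an ambiguity flag.  Frequencies are altered samples / total
    per (gene, type).
    """
    calls = []
    for gene, (chrom, gstart, gend) in sorted(gene_coords.items()):
        for sample in samples:
            seg = retained[(retained["chromosome"] == chrom) & (retained["sample"] == sample)]
            overlap = np.minimum(seg["end"], gend) - np.maximum(seg["start"], gstart)
            seg = seg[overlap > 0]
            overlap = overlap[overlap > 0]
            ambiguous = False
            if seg.empty:
                state = "neutral"
            else:
                best = overlap.max()
                top_types = set(seg.loc[overlap == best, "type"])
                if len(top_types) > 1:
                    state, ambiguous = "neutral", True
                else:
                    state = top_types.pop()
            calls.append({"gene": gene, "sample": sample, "state": state, "ambiguous": ambiguous})
    call_df = pd.DataFrame(calls)

    freq_rows = []
    n_samples = len(samples)
    for gene, grp in call_df.groupby("gene", sort=True):
        for alt_type in ("gain", "loss", "cnLOH"):
            freq_rows.append(
                {
                    "gene": gene,
                    "type": alt_type,
                    "frequency": float((grp["state"] == alt_type).sum()) / n_samples,
                }
            )
    return call_df, pd.DataFrame(freq_rows)


def gistic_categorize(cn_value, bounds: tuple = GISTIC_BOUNDS):
    """Map log2(rel-to-ploidy + 1) values to GISTIC categories in {-2..2}.

    -2 homozygous deletion, -1 hemizygous deletion, 0 neutral, 1 gain,
    2 high-level amplification.  Monotone non-decreasing in the input.
    """
    arr = np.asarray(cn_value, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN copy-number value")
    b1, b2, b3, b4 = bounds
    cat = np.select(
        [arr < b1, arr < b2, arr <= b3, arr <= b4],
        [-2, -1, 0, 1],
        default=2,
    )
    return int(cat) if np.isscalar(cn_value) else cat


def convert_1based_inclusive(coords: Mapping[str, tuple]) -> dict:
    """Convert gene coordinates from 1-based inclusive to 0-based half-open."""
    return {g: (c, s - 1, e) for g, (c, s, e) in coords.items()}


def dependency_efficacy_selectivity(dep: pd.DataFrame, eps: float = 1e-9) -> pd.DataFrame:
    """Per-gene efficacy/selectivity summary of a dependency-score matrix.

    dep: genes x cell lines, more negative = stronger growth reduction.
    efficacy = 10th percentile of the gene's scores; selectivity =
    (median - 10th percentile) / (1.4826 * MAD + eps).  A constant row has
    selectivity 0 and is flagged.
    """
    if dep.shape[1] < 10:
        raise ValueError("need at least 10 cell lines per gene")
    vals = dep.to_numpy(dtype=float)
    p10 = np.percentile(vals, 10, axis=1)
    med = np.median(vals, axis=1)
    mad = stats.median_abs_deviation(vals, axis=1)
    constant = vals.std(axis=1) == 0
    selectivity = np.where(constant, 0.0, (med - p10) / (1.4826 * mad + eps))
    return pd.DataFrame(
        {
            "efficacy": p10,
            "selectivity": selectivity,
            "constant_row": constant,
        },
        index=dep.index,
    )
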