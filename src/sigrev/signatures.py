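"""Disease-signature construction from tumor-vs-normal expression.

The statistic is the empirical-Bayes moderated t: per-gene sample variances
are shrunk toward a scaled inverse-chi-square prior (d0, s0^2) fitted by
moment-matching on log variances, and the resulting t statistic gains d0
extra degrees of freedom.  Signatures are the up/down gene sets passing
|log2FC| > 1 and BH-adjusted p < 0.001, the cutoffs used throughout this
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

VALID_SCALES = ("log_intensity", "counts", "log2_tpm1")

#: sentinel for an infinite prior degrees of freedom (variances essentially
#: constant across genes; the moderated t degenerates to a z-style test).
D0_INF = np.inf


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with a declared value scale.

    values: DataFrame indexed by gene label with sample columns.
    scale:  one of ``log_intensity``, ``counts``, ``log2_tpm1``.
    groups: sample -> "tumor" | "normal".
    """

    values: pd.DataFrame
    scale: str
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene labels: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without group labels: {missing[:5]}")
        bad = set(self.groups.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.scale == "counts":
            vals = self.values.to_numpy()
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                bad_pos = np.argwhere((vals < 0) | ~np.isclose(vals, np.round(vals)))
                g, s = bad_pos[0]
                raise ValueError(
                    "counts matrix must hold non-negative integers; offending cell "
                    f"gene={self.values.index[g]!r} sample={self.values.columns[s]!r}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]


@dataclass
class VariancePrior:
    """Scaled inverse-chi-square prior on gene variances."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is the prior-free limit (ordinary pooled t); np.inf collapses
        # the test onto the prior variance alone
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative (np.inf allowed)")
        if not (self.s0_sq > 0 and np.isfinite(self.s0_sq)):
            raise ValueError("s0_sq must be positive and finite")


@dataclass
class DiseaseSignature:
    """Up/down gene sets with the full differential-expression table."""

    dataset_id: str
    up: frozenset
    down: frozenset
    table: pd.DataFrame
    empty_warning: bool = False

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")

    @property
    def genes(self) -> frozenset:
        return self.up | self.down

    def log2fc(self, genes: Iterable[str] | None = None) -> pd.Series:
        fc = self.table["log2FC"]
        return fc if genes is None else fc.reindex(list(genes))


def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudo-count, per sample."""
    lib = counts.sum(axis=0)
    return np.log2((counts + prior_count).div(lib + 1.0, axis=1) * 1e6)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log-convex scale)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires positive input")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def fit_variance_prior(sample_variances: Sequence[float], df_resid: int) -> VariancePrior:
    """Moment-match (d0, s0_sq) on log sample variances.

    With s^2 ~ s0^2 * chi2_df/df scaled by an inverse-chi-square prior, the
    log variances have mean log(s0^2) + digamma shifts and excess variance
    trigamma(d0/2) beyond the trigamma(df/2) sampling term; inverting the
    trigamma recovers d0.  Returns d0 = inf when the excess is non-positive.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    if s2.size < 50:
        raise ValueError("need at least 50 gene variances to fit the prior")
    if df_resid < 1:
        raise ValueError("df_resid must be >= 1")
    if (s2 <= 0).any() or not np.isfinite(s2).all():
        raise ValueError("all sample variances must be positive and finite")

    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df_resid / 2.0)
    if excess <= 0:
        # degenerate: variances (nearly) constant; the geometric mean IS the
        # prior variance
        return VariancePrior(d0=D0_INF, s0_sq=float(np.exp(np.mean(z))))
    half_d0 = _trigamma_inverse(float(excess))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_ttest(m: ExpressionMatrix, prior: VariancePrior | None = None) -> pd.DataFrame:
    """Per-gene moderated two-sample t between tumor and normal samples.

    Counts matrices are converted to log2-CPM (pseudo-count 0.5) internally.
    Returns a DataFrame indexed by gene with columns log2FC, t_mod, p, padj,
    mean_expr and a zero_variance flag.
    """
    tumor_samples = m.group_samples("tumor")
    normal_samples = m.group_samples("normal")
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise ValueError("need at least 2 samples per group")

    values = log_cpm(m.values) if m.scale == "counts" else m.values
    t_vals = values[tumor_samples].to_numpy(dtype=float)
    n_vals = values[normal_samples].to_numpy(dtype=float)
    n_t, n_n = t_vals.shape[1], n_vals.shape[1]
    df = n_t + n_n - 2

    mean_t = t_vals.mean(axis=1)
    mean_n = n_vals.mean(axis=1)
    log2fc = mean_t - mean_n
    ss = t_vals.var(axis=1, ddof=1) * (n_t - 1) + n_vals.var(axis=1, ddof=1) * (n_n - 1)
    s2 = ss / df

    if prior is None:
        positive = s2[s2 > 0]
        if positive.size >= 50:
            prior = fit_variance_prior(positive, df)
        else:
            prior = VariancePrior(d0=D0_INF, s0_sq=float(max(positive.mean(), 1e-12)))
    d0, s0_sq = prior.d0, prior.s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n_t + 1.0 / n_n))
    zero_var = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(zero_var, 0.0, log2fc / np.where(zero_var, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(zero_var, 1.0, p)

    out = pd.DataFrame(
        {
            "log2FC": log2fc,
            "t_mod": t_mod,
            "p": p,
            "padj": bh_adjust(p),
            "mean_expr": values.to_numpy(dtype=float).mean(axis=1),
            "zero_variance": zero_var,
        },
        index=values.index,
    )
    out.attrs["prior"] = prior
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any():
        raise ValueError("NaN p-values are not allowed")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def collapse_duplicate_genes(de: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated gene labels, keeping the row with the lowest p."""
    if not de.index.duplicated().any():
        return de
    keep = de.sort_values("p", kind="mergesort")
    keep = keep.loc[~keep.index.duplicated(keep="first")]
    return keep.loc[de.index.unique()]


def build_signature(
    de: pd.DataFrame,
    dataset_id: str,
    lfc_cut: float = 1.0,
    alpha: float = 0.001,
) -> DiseaseSignature:
    """Threshold a DE table into a signature: |log2FC| > lfc_cut, padj < alpha."""
    if de.empty:
        raise ValueError("empty DE table")
    de = collapse_duplicate_genes(de)
    sig_mask = de["padj"] < alpha
    up = frozenset(de.index[sig_mask & (de["log2FC"] > lfc_cut)])
    down = frozenset(de.index[sig_mask & (de["log2FC"] < -lfc_cut)])
    empty = not up and not down
    if empty:
        warnings.warn(
            f"signature {dataset_id!r} has empty up and down sets; "
            "downstream reversal scoring requires both",
            stacklevel=2,
        )
    return DiseaseSignature(dataset_id=dataset_id, up=up, down=down, table=de, empty_warning=empty)


def select_matched_normals(
    tumors: ExpressionMatrix,
    normal_pool: ExpressionMatrix,
    k: int,
    n_components: int = 20,
) -> list[str]:
    """Pick the k pool samples most correlated with the tumor cohort.

    Both cohorts are projected into a PCA latent space fitted on the pooled
    samples; each pool sample is scored by its median Spearman correlation
    to the tumor samples in that space.  Ties break by sample label.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(normal_pool.samples):
        raise ValueError("k exceeds normal pool size")
    shared = tumors.genes.intersection(normal_pool.genes)
    if len(shared) < 500:
        raise ValueError(f"shared gene universe too small ({len(shared)} < 500)")

    t_mat = tumors.values.loc[shared].to_numpy(dtype=float).T
    p_mat = normal_pool.values.loc[shared].to_numpy(dtype=float).T
    combined = np.vstack([t_mat, p_mat])
    n_comp = min(n_components, combined.shape[0] - 1, combined.shape[1])
    latent = PCA(n_components=n_comp, svd_solver="full").fit_transform(combined)
    t_lat, p_lat = latent[: t_mat.shape[0]], latent[t_mat.shape[0]:]

    # Spearman = Pearson on within-vector component ranks
    t_rank = stats.rankdata(t_lat, axis=1)
    p_rank = stats.rankdata(p_lat, axis=1)

    def _standardize(a: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(a, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return a / norm

    corr = _standardize(p_rank) @ _standardize(t_rank).T  # pool x tumor
    score = np.median(corr, axis=1)
    labels = list(normal_pool.samples)
    order = sorted(range(len(labels)), key=lambda i: (-score[i], labels[i]))
    return [labels[i] for i in order[:k]]


@dataclass
class SignatureOverlap:
    """Cross-signature overlap summary of U∪D memberships."""

    pairwise_counts: pd.DataFrame
    shared_by_all: list[str]
    degree_counts: pd.Series  # genes present in >= m signatures
    top_ranking: pd.DataFrame  # shared genes ranked by L1 norm of |log2FC|


def intersect_signatures(sigs: Sequence[DiseaseSignature]) -> SignatureOverlap:
    """Pairwise/k-way overlaps and the consensus top-DEG ranking.

    Genes present in every signature are ranked by the L1 norm of their
    |log2FC| vector across signatures, descending (largest consistent
    deregulation first).
    """
    if len(sigs) < 2:
        raise ValueError("need at least 2 signatures")
    ids = [s.dataset_id for s in sigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset_ids")

    members = {s.dataset_id: s.genes for s in sigs}
    pairwise = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for a in ids:
        for b in ids:
            pairwise.loc[a, b] = len(members[a] & members[b])

    all_genes = set().union(*members.values())
    degree = {g: sum(g in members[i] for i in ids) for g in all_genes}
    degree_counts = pd.Series(
        {m: sum(1 for d in degree.values() if d >= m) for m in range(1, len(ids) + 1)},
        name="n_genes",
    )
    shared = sorted(g for g, d in degree.items() if d == len(ids))

    l1 = {}
    for g in shared:
        l1[g] = float(sum(abs(s.table.loc[g, "log2FC"]) for s in sigs if g in s.table.index))
    top = (
        pd.DataFrame({"gene": shared, "l1_log2fc": [l1[g] for g in shared]})
        .sort_values(["l1_log2fc", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return SignatureOverlap(
        pairwise_counts=pairwise,
        shared_by_all=shared,
        degree_counts=degree_counts,
        top_ranking=top,
    )
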