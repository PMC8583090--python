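"""Synthetic cohorts, perturbation libraries and screens with known truth.

Every generator is deterministic given (config, seed).  A single seed drives
all generators through a documented split scheme based on
``numpy.random.SeedSequence(seed, spawn_key=(k,))``:

    k = 0  ground truth (DE genes, signs, reverser drugs)
    k = 1  expression cohorts (sub-keyed by dataset index)
    k = 2  perturbation library
    k = 3  viability screen and cell-line profiles
    k = 4  copy-number segments
    k = 5  gene-set library

so any stage can be regenerated independently of the others.  The ground
truth (planted fold changes, reverser identities, the biomarker link) is a
separate channel consumed only by tests and acceptance checks, never by the
analysis operations themselves.

The defaults emulate the study conditions this pipeline is built around: a
tumor/normal cohort of 30+30 with ~10% differentially expressed genes at
|log2FC| = 2, a 200-drug library with 20 planted reversers at strength 0.8
profiled over 4 cell lines and an 8-point 4-fold dose ladder from 10 uM down
to ~600 pM, and a 30-line viability screen whose potency for six linked
drugs is tied to the copy number of a planted biomarker gene (labelled
TOP2A) with Pearson r = -0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetLibrary
from .models import CellLineProfile, DoseResponseCurve
from .reversal import PerturbationLibrary
from .signatures import D0_INF, ExpressionMatrix

#: default 8-point 4-fold dilution ladder from 10 uM (down to ~600 pM)
DEFAULT_DOSE_LADDER = tuple(10.0 / 4.0**k for k in range(8))

#: synthetic coordinates (0-based half-open) of the planted biomarker gene
TOP2A_COORDS = ("chr17", 38_000_000, 38_030_000)

BIOMARKER_LABEL = "TOP2A"


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation knobs; defaults are the pipeline's study conditions."""

    n_genes: int = 978
    n_tumor: int = 30
    n_normal: int = 30
    frac_de: float = 0.1
    lfc_mean: float = 2.0
    d0: float = 4.0
    s0_sq: float = 0.05
    n_drugs: int = 200
    n_reversers: int = 20
    reversal_strength: float = 0.8
    cell_lines: tuple = ("CL1", "CL2", "CL3", "CL4")
    dose_ladder: tuple = DEFAULT_DOSE_LADDER
    seed: int = 0
    # secondary knobs referenced by the generators
    dispersion: float = 0.1  # NB dispersion for counts mode
    profile_noise_sd: float = 0.5
    profile_times: tuple = (24.0,)
    n_screen_lines: int = 30
    n_linked_drugs: int = 6
    planted_cn_sensitivity_r: float = -0.8
    viability_noise_sd: float = 0.05
    n_tumorlike_lines: int = 10
    tumorlike_scale: float = 0.8
    n_segments: int = 60

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValueError(f"non-finite value for field {f.name!r}")
        for name in ("n_genes", "n_tumor", "n_normal", "n_drugs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.frac_de < 1):
            raise ValueError("frac_de must lie in [0, 1)")
        if self.frac_de > 0 and self.frac_de * self.n_genes < 10:
            raise ValueError("frac_de * n_genes must be at least 10")
        if not (0 <= self.n_reversers <= self.n_drugs):
            raise ValueError("n_reversers must lie in [0, n_drugs]")
        if not (0 <= self.reversal_strength <= 1):
            raise ValueError("reversal_strength must lie in [0, 1]")
        if not (-1 <= self.planted_cn_sensitivity_r <= 0):
            raise ValueError("planted_cn_sensitivity_r must lie in [-1, 0]")
        ladder = np.asarray(self.dose_ladder, dtype=float)
        if ladder.size < 1 or (ladder <= 0).any() or (np.diff(ladder) >= 0).any():
            raise ValueError("dose_ladder must be strictly decreasing and positive")
        if self.d0 <= 0 or self.s0_sq <= 0:
            raise ValueError("d0 and s0_sq must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects; read only by tests, never by analysis operations."""

    de_genes: dict  # gene -> signed log2FC
    reverser_drugs: frozenset
    biomarker_gene: str
    planted_cn_sensitivity_r: float


def _rng(config: SimulationConfig, key: int, *subkeys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key, *subkeys)))


def gene_labels(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, config.n_genes + 1)]


def drug_labels(config: SimulationConfig) -> list[str]:
    return [f"drug_{i:03d}" for i in range(1, config.n_drugs + 1)]


def make_ground_truth(config: SimulationConfig) -> tuple[list[str], GroundTruth]:
    """Draw the planted DE genes, reverser drugs and biomarker identity.

    Returns the final gene universe (the planted biomarker gene is relabelled
    TOP2A) and the GroundTruth record.
    """
    rng = _rng(config, 0)
    genes = gene_labels(config)
    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = np.sort(rng.choice(config.n_genes, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = signs * config.lfc_mean

    biomarker = BIOMARKER_LABEL
    up_positions = [i for i, s in zip(de_idx, signs) if s > 0]
    if up_positions:
        genes[up_positions[0]] = biomarker
    elif n_de:
        genes[de_idx[0]] = biomarker
    de_genes = {genes[i]: float(v) for i, v in zip(de_idx, lfc)}

    drugs = drug_labels(config)
    rev_idx = rng.choice(config.n_drugs, size=config.n_reversers, replace=False)
    reversers = frozenset(drugs[i] for i in rev_idx)
    return genes, GroundTruth(
        de_genes=de_genes,
        reverser_drugs=reversers,
        biomarker_gene=biomarker,
        planted_cn_sensitivity_r=config.planted_cn_sensitivity_r,
    )


def _gene_variances(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    # scaled inverse-chi-square(d0, s0_sq): s^2 = d0 * s0_sq / chi2_d0
    if np.isinf(config.d0):
        return np.full(config.n_genes, config.s0_sq)
    return config.d0 * config.s0_sq / rng.chisquare(config.d0, size=config.n_genes)


def generate_expression_cohort(
    config: SimulationConfig,
    scale: str = "log_intensity",
    dataset_index: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Tumor/normal cohort with planted signed log2 fold changes.

    log-intensity mode: per-gene Gaussian with variance drawn from the
    scaled inverse-chi-square(d0, s0_sq) prior; tumor means are shifted by
    the planted log2FC.  counts mode: negative binomial with gene-wise means
    consistent with the same fold changes (dispersion ``config.dispersion``).
    """
    if scale not in ("log_intensity", "counts"):
        raise ValueError(f"scale must be 'log_intensity' or 'counts', got {scale!r}")
    genes, truth = make_ground_truth(config)
    rng = _rng(config, 1, dataset_index)

    baseline = rng.normal(7.0, 1.0, size=config.n_genes)
    lfc_vec = np.array([truth.de_genes.get(g, 0.0) for g in genes])
    n_t, n_n = config.n_tumor, config.n_normal
    samples = [f"T{i:03d}" for i in range(1, n_t + 1)] + [f"N{i:03d}" for i in range(1, n_n + 1)]
    groups = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=samples)

    if scale == "log_intensity":
        sd = np.sqrt(_gene_variances(config, rng))
        normal_vals = baseline[:, None] + sd[:, None] * rng.standard_normal((config.n_genes, n_n))
        tumor_vals = (
            (baseline + lfc_vec)[:, None]
            + sd[:, None] * rng.standard_normal((config.n_genes, n_t))
        )
        values = np.hstack([tumor_vals, normal_vals])
        matrix_scale = "log_intensity"
    else:
        mu_normal = 2.0 ** baseline
        mu_tumor = mu_normal * 2.0 ** lfc_vec
        disp = config.dispersion
        size_param = 1.0 / disp

        def _nb(mu: np.ndarray, n_samples: int) -> np.ndarray:
            p = size_param / (size_param + mu[:, None])
            return rng.negative_binomial(size_param, p, size=(config.n_genes, n_samples))

        values = np.hstack([_nb(mu_tumor, n_t), _nb(mu_normal, n_n)])
        matrix_scale = "counts"

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        scale=matrix_scale,
        groups=groups,
    )
    return matrix, truth


def generate_signature_cohorts(
    config: SimulationConfig,
    n_datasets: int,
    scale: str = "log_intensity",
) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """Several cohorts sharing one planted truth (a common DE core)."""
    cohorts = []
    truth = None
    for i in range(n_datasets):
        m, truth = generate_expression_cohort(config, scale=scale, dataset_index=i)
        cohorts.append(m)
    return cohorts, truth


def potency(dose_um: np.ndarray | float) -> np.ndarray | float:
    """Saturating dose-potency: dose / (dose + 1 uM); ~0.91 at 10 uM."""
    return dose_um / (dose_um + 1.0)


def generate_perturbation_library(
    config: SimulationConfig,
    truth: GroundTruth,
) -> PerturbationLibrary:
    """Drug-perturbation differential profiles with planted reversers.

    Reverser profiles subtract ``strength * potency(dose) * planted log2FC``
    from Gaussian noise; all other drugs are pure noise.  Each drug is
    profiled on every cell line x dose x time combination.
    """
    if not config.cell_lines:
        raise ValueError("cell_lines must be nonempty")
    if config.n_reversers > 0 and not truth.de_genes:
        raise ValueError("truth.de_genes must be nonempty when n_reversers > 0")
    n_combo = len(config.cell_lines) * len(config.dose_ladder) * len(config.profile_times)
    if n_combo < 3:
        raise ValueError("each drug needs at least 3 profiles (cell line x dose x time)")

    genes, _ = make_ground_truth(config)
    lfc_vec = np.array([truth.de_genes.get(g, 0.0) for g in genes])
    drugs = drug_labels(config)
    rng = _rng(config, 2)

    meta_rows = []
    for drug in drugs:
        for cl in config.cell_lines:
            for dose in config.dose_ladder:
                for t in config.profile_times:
                    meta_rows.append((drug, cl, dose, t))
    meta = pd.DataFrame(meta_rows, columns=["drug", "cell_line", "dose_uM", "time_h"])

    values = rng.normal(0.0, config.profile_noise_sd, size=(len(meta), config.n_genes))
    is_rev = meta["drug"].isin(truth.reverser_drugs).to_numpy()
    pot = potency(meta["dose_uM"].to_numpy())
    signal = -config.reversal_strength * pot[:, None] * lfc_vec[None, :]
    values[is_rev] += signal[is_rev]
    return PerturbationLibrary(meta=meta, values=values, genes=genes)


@dataclass
class ViabilityScreen:
    """Dose-response curves plus matched cell-line CN/expression profiles."""

    curves: list
    profiles: list
    cn_table: pd.DataFrame  # genes x lines, log2(rel-to-ploidy + 1)
    expression_table: pd.DataFrame  # genes x lines, log2(TPM + 1)
    linked_drugs: list
    unlinked_drugs: list
    tumorlike_lines: list


def generate_viability_screen(config: SimulationConfig, truth: GroundTruth) -> ViabilityScreen:
    """Hill-type viability curves with a planted biomarker-sensitivity link.

    For the linked drugs (the first reversers, sorted), the per-line curve
    amplitude is correlated with the line's biomarker copy number so that
    Pearson r between CN and the AUC sensitivity equals the planted value in
    expectation; control drugs get independent amplitudes.  A subset of
    lines is built "tumor-like" (expression shifted along the planted
    signature) for model-line selection.
    """
    if len(config.dose_ladder) < 2:
        raise ValueError("dose_ladder needs at least 2 points")
    rng = _rng(config, 3)
    genes, _ = make_ground_truth(config)
    lfc_vec = np.array([truth.de_genes.get(g, 0.0) for g in genes])
    lines = [f"LINE{i:02d}" for i in range(1, config.n_screen_lines + 1)]
    n_lines = len(lines)

    cn_biomarker = rng.normal(1.0, 0.15, size=n_lines)
    z = (cn_biomarker - cn_biomarker.mean()) / cn_biomarker.std()

    reversers = sorted(truth.reverser_drugs)
    others = sorted(set(drug_labels(config)) - truth.reverser_drugs)
    linked = reversers[: config.n_linked_drugs]
    unlinked = others[: config.n_linked_drugs]

    r = config.planted_cn_sensitivity_r
    amp_base, amp_spread = -2.0, 0.7
    doses = np.asarray(config.dose_ladder, dtype=float)
    pot = potency(doses)

    curves = []
    for drug in linked + unlinked:
        eps = rng.standard_normal(n_lines)
        if drug in linked:
            mix = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * eps
        else:
            mix = eps
        # a drug is at worst inert: cap the curve amplitude at 0 so viability
        # log2FC is non-increasing in dose for every drug/line
        amplitude = np.minimum(amp_base + amp_spread * mix, 0.0)
        noise = rng.normal(0.0, config.viability_noise_sd, size=(n_lines, doses.size))
        for i, cl in enumerate(lines):
            v = amplitude[i] * pot + noise[i]
            curves.append(
                DoseResponseCurve(
                    drug=drug,
                    cell_line=cl,
                    points=pd.DataFrame({"dose_uM": doses, "viability_log2fc": v}),
                )
            )

    # gene-level CN: biomarker row carries the planted values, rest near-neutral
    cn = rng.normal(1.0, 0.05, size=(config.n_genes, n_lines))
    bio_idx = genes.index(truth.biomarker_gene)
    cn[bio_idx] = cn_biomarker
    cn_table = pd.DataFrame(cn, index=genes, columns=lines)

    baseline = rng.uniform(3.0, 8.0, size=config.n_genes)
    expr = baseline[:, None] + rng.normal(0.0, 0.3, size=(config.n_genes, n_lines))
    tumorlike = lines[: config.n_tumorlike_lines]
    expr[:, : config.n_tumorlike_lines] += config.tumorlike_scale * lfc_vec[:, None]
    expr[bio_idx] = np.clip(5.0 + 3.0 * (cn_biomarker - 1.0) + rng.normal(0, 0.1, n_lines), 0, None)
    expr = np.clip(expr, 0.0, None)
    expression_table = pd.DataFrame(expr, index=genes, columns=lines)

    profiles = [
        CellLineProfile(
            cell_line=cl,
            expression=expression_table[cl],
            cn=cn_table[cl],
            lineage="colorectal",
        )
        for cl in lines
    ]
    return ViabilityScreen(
        curves=curves,
        profiles=profiles,
        cn_table=cn_table,
        expression_table=expression_table,
        linked_drugs=list(linked),
        unlinked_drugs=list(unlinked),
        tumorlike_lines=list(tumorlike),
    )


def generate_cn_segments(
    config: SimulationConfig,
    n_samples: int = 32,
    n_gene_gains: int = 8,
) -> pd.DataFrame:
    """Copy-number segments straddling the retention thresholds.

    Always contains boundary fixtures (loss with 24 and 25 probes, gain with
    49 and 50 probes, cnLOH of 4.9 and 5.0 Mb) and, for the first
    ``n_gene_gains`` samples, a retained gain covering the synthetic TOP2A
    locus.  Random filler segments avoid chr17 so gene-level calls at that
    locus reflect only the planted gains.  Total row count equals
    ``config.n_segments``.
    """
    rng = _rng(config, 4)
    samples = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    chrom17, g_start, g_end = TOP2A_COORDS

    rows = [
        # boundary fixtures (sample S01, chr1/chr2)
        {"chromosome": "chr1", "start": 1_000_000, "end": 1_500_000, "probe_count": 24, "type": "loss", "sample": "S01"},
        {"chromosome": "chr1", "start": 2_000_000, "end": 2_500_000, "probe_count": 25, "type": "loss", "sample": "S01"},
        {"chromosome": "chr1", "start": 3_000_000, "end": 3_500_000, "probe_count": 49, "type": "gain", "sample": "S01"},
        {"chromosome": "chr1", "start": 4_000_000, "end": 4_500_000, "probe_count": 50, "type": "gain", "sample": "S01"},
        {"chromosome": "chr2", "start": 1_000_000, "end": 5_900_000, "probe_count": 500, "type": "cnLOH", "sample": "S01"},
        {"chromosome": "chr2", "start": 10_000_000, "end": 15_000_000, "probe_count": 500, "type": "cnLOH", "sample": "S01"},
    ]
    rows[4]["end"] = rows[4]["start"] + 4_900_000  # 4.9 Mb
    for s in samples[:n_gene_gains]:
        rows.append(
            {
                "chromosome": chrom17,
                "start": g_start - 100_000,
                "end": g_end + 100_000,
                "probe_count": 120,
                "type": "gain",
                "sample": s,
            }
        )

    filler_chroms = [f"chr{c}" for c in range(3, 13)]
    while len(rows) < config.n_segments:
        seg_type = rng.choice(["gain", "loss", "cnLOH"])
        start = int(rng.integers(1_000_000, 50_000_000))
        length = int(rng.integers(100_000, 10_000_000))
        rows.append(
            {
                "chromosome": str(rng.choice(filler_chroms)),
                "start": start,
                "end": start + length,
                "probe_count": int(rng.integers(5, 200)),
                "type": str(seg_type),
                "sample": str(rng.choice(samples)),
            }
        )
    if len(rows) > config.n_segments:
        raise ValueError(
            f"n_segments={config.n_segments} too small for the fixed fixtures ({len(rows)})"
        )
    return pd.DataFrame(rows)


def generate_geneset_library(
    config: SimulationConfig,
    truth: GroundTruth,
    n_sets: int = 20,
    set_size: int = 30,
) -> GeneSetLibrary:
    """GMT-style library: one true pathway inside the DE genes plus decoys."""
    genes, _ = make_ground_truth(config)
    if set_size > config.n_genes:
        raise ValueError("set_size exceeds the gene universe")
    rng = _rng(config, 5)
    universe = frozenset(genes)

    de_sorted = sorted(truth.de_genes)
    true_size = min(set_size, len(de_sorted))
    if true_size == 0:
        raise ValueError("cannot plant a true pathway without DE genes")
    sets = {"true_pathway": frozenset(de_sorted[:true_size])}
    gene_arr = np.array(genes)
    for i in range(1, n_sets):
        sets[f"decoy_{i:02d}"] = frozenset(rng.choice(gene_arr, size=set_size, replace=False))
    return GeneSetLibrary(name="synthetic", sets=sets, universe=universe)
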