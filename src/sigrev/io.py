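"""Readers/writers for the pipeline's plain-text interchange formats.

Expression matrices are genes x samples TSV with a one-line ``#scale=``
header and a ``<path>.samples.tsv`` sidecar holding the sample -> group
labels.  Gene-set libraries use standard GMT.  Perturbation libraries and
copy-number segments travel as long/BED-like TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .enrichment import GeneSetLibrary
from .reversal import PerturbationLibrary
from .signatures import VALID_SCALES, ExpressionMatrix

SCALE_HEADER = "#scale="


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{SCALE_HEADER}{m.scale}\n")
        m.values.to_csv(fh, sep="\t", index_label="gene")
    sidecar = path.with_suffix(path.suffix + ".samples.tsv")
    pd.DataFrame({"sample": m.groups.index, "group": m.groups.to_numpy()}).to_csv(
        sidecar, sep="\t", index=False
    )


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(SCALE_HEADER):
            raise ValueError(
                f"{path}: missing required '{SCALE_HEADER}<scale>' header line"
            )
        scale = first[len(SCALE_HEADER):]
        if scale not in VALID_SCALES:
            raise ValueError(f"{path}: unknown scale {scale!r}")
        header = fh.readline().rstrip("\n").split("\t")
        sample_names = header[1:]
        if len(set(sample_names)) != len(sample_names):
            raise ValueError(f"{path}: duplicate sample labels")
        values = pd.read_csv(fh, sep="\t", header=None, names=header, index_col="gene")
    for col in values.columns:
        bad = pd.to_numeric(values[col], errors="coerce").isna() & values[col].notna()
        if bad.any():
            gene = values.index[bad][0]
            raise ValueError(f"{path}: non-numeric cell at gene={gene!r} sample={col!r}")
    if scale == "counts":
        numeric = values.astype(float)
        frac = numeric != numeric.round()
        if frac.any().any():
            col = frac.any(axis=0).idxmax()
            gene = numeric.index[frac[col]][0]
            raise ValueError(
                f"{path}: counts must be integers; non-integer value at "
                f"gene={gene!r} sample={col!r}"
            )
        values = numeric.round().astype(int)

    sidecar = path.with_suffix(path.suffix + ".samples.tsv")
    ann = pd.read_csv(sidecar, sep="\t")
    groups = pd.Series(ann["group"].to_numpy(), index=ann["sample"])
    return ExpressionMatrix(values=values, scale=scale, groups=groups)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(library.sets):
            members = "\t".join(sorted(library.sets[term]))
            fh.write(f"{term}\t{library.name}\t{members}\n")


def read_gmt(path: str | Path, universe: set | None = None, name: str = "") -> GeneSetLibrary:
    """Parse a GMT file; duplicate members within a set collapse with a warning.

    The background universe defaults to the union of all set members unless
    supplied explicitly.
    """
    path = Path(path)
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            term, desc, members = parts[0], parts[1], parts[2:]
            members = [g for g in members if g]
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {term!r}")
            unique = set(members)
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: {len(members) - len(unique)} duplicate members "
                    f"collapsed in set {term!r}",
                    stacklevel=2,
                )
            sets[term] = frozenset(unique)
            name = name or desc
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetLibrary(name=name, sets=sets, universe=frozenset(universe))


def write_perturbation_library(library: PerturbationLibrary, path: str | Path) -> None:
    library.to_long().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_perturbation_library(path: str | Path) -> PerturbationLibrary:
    return PerturbationLibrary.from_long(pd.read_csv(path, sep="\t"))


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    cols = ["chromosome", "start", "end", "probe_count", "type", "sample"]
    segments[[c for c in cols if c in segments.columns]].to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
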