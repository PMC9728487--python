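"""Readers and writers for the on-disk formats.

All tabular outputs are TSV with '#'-prefixed provenance header lines
(tool version, seed, options), a decimal point and no thousands
separators; a missing value is an empty cell, never 0 or an NA string.
Peptide tables additionally support a MaxQuant-compatibility dialect
("Sequence", "Proteins", "Intensity <sample>"), where intensity 0 is read
as missing, matching that software's convention.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import GeneSet
from .hierarchy import ConditionHierarchy
from .phenotype import ViabilitySeries

SAMPLE_SEP = "__"


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# survscore {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def _write_tsv(df: pd.DataFrame, path, meta: dict | None, index: bool) -> None:
    path = Path(path)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, na_rep="")
    path.write_text("\n".join(_header_lines(meta)) + "\n" + buf.getvalue())


# -- peptide intensity tables ---------------------------------------------


def _sample_label(col: tuple) -> str:
    return SAMPLE_SEP.join(str(c) for c in col)


def write_peptide_table(
    table: pd.DataFrame, path, dialect: str = "native", meta: dict | None = None
) -> None:
    if dialect != "native":
        raise ValueError("only the native dialect is written")
    flat = table.copy()
    flat.columns = [_sample_label(c) for c in table.columns]
    flat = flat.reset_index()
    _write_tsv(flat, path, meta, index=False)


def _split_sample(label: str, path, colno: int) -> tuple:
    parts = label.split(SAMPLE_SEP)
    if len(parts) == 2:
        cond, rep = parts
        return cond, int(rep)
    if len(parts) == 3:
        cond, rep, channel = parts
        if channel not in ("light", "heavy"):
            raise ValueError(f"{path}: unknown channel {channel!r} in column {colno}")
        return cond, int(rep), channel
    raise ValueError(
        f"{path}: sample column {label!r} (column {colno}) is not "
        f"'<condition>{SAMPLE_SEP}<replicate>'"
    )


def read_peptide_table(path, dialect: str = "native") -> pd.DataFrame:
    """Peptide intensity table with (condition, replicate[, channel]) columns.

    Native dialect: columns peptide, protein, then sample columns.
    MaxQuant dialect: "Sequence", "Proteins", "Intensity <sample>"; zero
    intensities are read as missing.
    """
    if dialect not in ("native", "maxquant"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if dialect == "maxquant":
        if not {"Sequence", "Proteins"} <= set(df.columns):
            raise ValueError(f"{path}: MaxQuant dialect needs Sequence and Proteins")
        ren = {"Sequence": "peptide", "Proteins": "protein"}
        samples = [c for c in df.columns if c.startswith("Intensity ")]
        if not samples:
            raise ValueError(f"{path}: no 'Intensity <sample>' columns found")
        ren.update({c: c[len("Intensity "):] for c in samples})
        df = df[["Sequence", "Proteins", *samples]].rename(columns=ren)
        value_cols = [ren[c] for c in samples]
        df[value_cols] = df[value_cols].replace(0, np.nan)
    else:
        if list(df.columns[:2]) != ["peptide", "protein"]:
            raise ValueError(
                f"{path}: native dialect must start with columns peptide, protein"
            )
    dup = df["peptide"].duplicated(keep=False)
    if dup.any():
        # +2: header line plus 1-based numbering (provenance lines are
        # stripped by the reader, so line numbers are post-header)
        lines = [int(i) + 2 for i in df.index[dup]]
        raise ValueError(f"{path}: duplicate (peptide, sample) entries at lines {lines}")
    sample_cols = [c for c in df.columns if c not in ("peptide", "protein")]
    parsed = [_split_sample(c, path, i + 3) for i, c in enumerate(sample_cols)]
    width = {len(p) for p in parsed}
    if len(width) > 1:
        raise ValueError(f"{path}: mixed sample column formats")
    names = ["condition", "replicate"] + (["channel"] if width == {3} else [])
    out = df.set_index(["peptide", "protein"])[sample_cols]
    out.columns = pd.MultiIndex.from_tuples(parsed, names=names)
    out = out.replace(0, np.nan)
    return out


# -- condition metadata ----------------------------------------------------


def write_condition_table(
    hierarchy: ConditionHierarchy, path, meta: dict | None = None
) -> None:
    _write_tsv(hierarchy.to_frame(), path, meta, index=False)


def read_condition_table(path) -> ConditionHierarchy:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ConditionHierarchy.from_frame(df)


# -- gene sets -------------------------------------------------------------


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    lines = []
    for gs in sorted(gene_sets, key=lambda g: g.set_id):
        members = "\t".join(sorted(gs.members))
        lines.append(f"{gs.set_id}\t{gs.name}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path, namespace: str = "custom") -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, name, members")
            sets.append(
                GeneSet(
                    set_id=cols[0],
                    name=cols[1],
                    namespace=namespace,
                    members=frozenset(c for c in cols[2:] if c),
                )
            )
    return sets


def read_annotation_files(
    gmt=None, obo=None, gaf=None, relations=("is_a", "part_of")
) -> list[GeneSet]:
    """Gene sets from either a GMT file or an OBO + GAF pair, never both."""
    from .enrichment import build_gene_sets_from_obo_gaf

    if gmt is not None and (obo is not None or gaf is not None):
        raise ValueError("give either a GMT file or an OBO+GAF pair, not both")
    if gmt is not None:
        return read_gmt(gmt)
    if obo is None or gaf is None:
        raise ValueError("OBO and GAF files are both required")
    return build_gene_sets_from_obo_gaf(obo, gaf, relations=relations)


# -- viability -------------------------------------------------------------


def write_viability_csv(series: list[ViabilitySeries], path) -> None:
    df = pd.concat([s.to_frame() for s in series], ignore_index=True)
    Path(path).write_text(df.to_csv(index=False))


def read_viability_csv(path) -> list[ViabilitySeries]:
    df = pd.read_csv(path, comment="#")
    required = {"condition_id", "replicate", "time_days", "cfu_per_ml"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: viability CSV needs columns {sorted(required)}")
    out = []
    for (cond, rep), grp in df.groupby(["condition_id", "replicate"], sort=True):
        grp = grp.sort_values("time_days")
        out.append(
            ViabilitySeries(
                condition_id=str(cond),
                replicate=str(rep),
                times=grp["time_days"].to_numpy(),
                cfu=grp["cfu_per_ml"].to_numpy(),
            )
        )
    return out


# -- derived tables --------------------------------------------------------


def write_pair_stats(stats: pd.DataFrame, path, meta: dict | None = None) -> None:
    cols = [
        "protein_id",
        "perturbation",
        "dataset_id",
        "cond_high_death",
        "cond_low_death",
        "log2fc",
        "pvalue",
    ]
    _write_tsv(stats[cols].sort_values(["protein_id", "dataset_id"]), path, meta, False)


def read_pair_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_scores(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(table.sort_index(), path, meta, index=True)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="protein_id")


def write_enrichment(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(table.sort_values("set_id"), path, meta, index=False)
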