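"""Readers/writers for the tabular formats the pipeline consumes and emits.

The pipeline begins at differential-expression summary tables (one row per
gene: identifier, symbol, log2 fold change, mean normalized expression, P
value) and gene sets in GMT format.  Everything downstream -- ortholog
re-keying, per-cluster scoring, reversal statistics -- consumes these
containers.  All result tables are TSV; run metadata (configuration and
seed) travels in JSON sidecars so that reruns are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("degrank")

__all__ = [
    "FormatError",
    "IntegrityError",
    "ParameterError",
    "DEGTable",
    "GeneSet",
    "AnalysisConfig",
    "read_deg_table",
    "write_deg_table",
    "read_gmt",
    "write_gmt",
    "write_scorecards",
    "DEG_COLUMNS",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class IntegrityError(ValueError):
    """Parsed content violates a data invariant (e.g. duplicate keys)."""


class ParameterError(ValueError):
    """An argument is outside its admissible range."""


#: canonical column order of a DEG table
DEG_COLUMNS = ("gene_id", "symbol", "log2fc", "mean_expr", "p_value", "p_adj")

# 17 significant digits round-trips any IEEE double exactly.
_FLOAT_FMT = "%.17g"


@dataclass
class DEGTable:
    """One differential-expression comparison (bulk or per cell cluster).

    ``data`` holds one row per gene with columns :data:`DEG_COLUMNS`;
    ``p_adj`` may be NaN throughout when no adjusted values are available.
    """

    comparison_label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DEG_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"DEG table missing columns: {missing}")
        self.data = self.data.loc[:, list(DEG_COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        d = self.data
        dup = d["gene_id"][d["gene_id"].duplicated()]
        if len(dup):
            raise IntegrityError(
                f"duplicate gene_id in {self.comparison_label!r}: "
                f"{sorted(set(dup))[:5]}"
            )
        p = d["p_value"].to_numpy(float)
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise IntegrityError(f"p_value outside [0,1] in {self.comparison_label!r}")
        if np.any(d["mean_expr"].to_numpy(float) < 0):
            raise IntegrityError(f"negative mean_expr in {self.comparison_label!r}")
        if not np.all(np.isfinite(d["log2fc"].to_numpy(float))):
            raise IntegrityError(f"non-finite log2fc in {self.comparison_label!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.data["gene_id"])

    def filter_expressed(self, mean_expr_floor: float) -> "DEGTable":
        """Drop low-expression genes: keep rows with mean_expr > floor.

        The floor is exclusive-keep (a gene exactly at the floor is removed),
        mirroring the baseMean <= 20 exclusion used upstream of every
        correlation and direction test.
        """
        kept = self.data[self.data["mean_expr"].to_numpy(float) > mean_expr_floor]
        return DEGTable(self.comparison_label, kept.copy())

    def significant(self, p_threshold: float) -> "DEGTable":
        """Rows called differentially expressed at the unadjusted threshold."""
        kept = self.data[self.data["p_value"].to_numpy(float) < p_threshold]
        return DEGTable(self.comparison_label, kept.copy())

    def split_directions(self, p_threshold: float) -> tuple["DEGTable", "DEGTable"]:
        """(upregulated, downregulated) DEG tables at the given threshold.

        Genes with log2fc exactly 0 are in neither direction.
        """
        sig = self.significant(p_threshold).data
        up = sig[sig["log2fc"].to_numpy(float) > 0]
        down = sig[sig["log2fc"].to_numpy(float) < 0]
        return (
            DEGTable(f"{self.comparison_label}.up", up.copy()),
            DEGTable(f"{self.comparison_label}.down", down.copy()),
        )

    def log2fc_series(self) -> pd.Series:
        return pd.Series(
            self.data["log2fc"].to_numpy(float),
            index=self.data["gene_id"].to_numpy(),
            name=self.comparison_label,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. the 185-member ASD exome risk-gene set)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise IntegrityError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and reproducibility knobs shared across the pipeline.

    deg_p_threshold
        Unadjusted P below which a gene counts as differentially expressed.
    mean_expr_floor
        Mean-expression (baseMean) floor; genes at or below it are excluded.
    top_n_degs
        How many top DEGs (by unadjusted P) feed the heritability slot.
    mc_reps
        Monte-Carlo / permutation replicate count for simulated tests.
    seed
        Root seed; every random draw in the package descends from it.
    """

    deg_p_threshold: float = 0.05
    mean_expr_floor: float = 20.0
    top_n_degs: int = 1000
    mc_reps: int = 2000
    seed: int = 0
    tie_break: str = "fisher"
    one_tailed_direction: str = "upper"

    def __post_init__(self) -> None:
        if not 0.0 < self.deg_p_threshold < 1.0:
            raise ParameterError("deg_p_threshold must be in (0, 1)")
        if self.top_n_degs < 1:
            raise ParameterError("top_n_degs must be >= 1")
        if self.mc_reps < 100:
            raise ParameterError("mc_reps must be >= 100")
        if self.tie_break != "fisher":
            raise ParameterError("tie_break must be 'fisher'")
        if self.one_tailed_direction != "upper":
            raise ParameterError("one_tailed_direction must be 'upper'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


def _parse_float(value) -> float:
    # correctly-rounded parse (pandas' fast to_numeric path is not
    # round-trip exact for 17-digit decimals)
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def _sniff_delimiter(header_line: str) -> str:
    has_tab = "\t" in header_line
    has_comma = "," in header_line
    if has_tab and has_comma:
        raise FormatError("ambiguous delimiter: header contains both tab and comma")
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    raise FormatError("could not detect delimiter (expected tab or comma)")


def read_deg_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    comparison_label: str | None = None,
) -> DEGTable:
    """Read a DEG summary table from a headered TSV/CSV file.

    ``column_map`` maps canonical field names (``gene_id``, ``symbol``,
    ``log2fc``, ``mean_expr``, ``p_value``, optionally ``p_adj``) to the
    source column names.  Omitted keys default to the canonical names;
    ``symbol`` falls back to ``gene_id`` and ``p_adj`` to NaN when absent.
    Rows whose numeric fields fail to parse or fall outside their admissible
    range are rejected and reported (with source row numbers) on the logger.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    sep = _sniff_delimiter(header.rstrip("\n"))
    raw = pd.read_csv(path, sep=sep, dtype=str)

    cmap = dict(column_map or {})
    mandatory = ("gene_id", "log2fc", "mean_expr", "p_value")
    for fieldname in mandatory:
        src = cmap.get(fieldname, fieldname)
        if src not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {src!r} ({fieldname})")

    out = pd.DataFrame()
    out["gene_id"] = raw[cmap.get("gene_id", "gene_id")].astype(str)
    sym_src = cmap.get("symbol", "symbol")
    out["symbol"] = (
        raw[sym_src].astype(str) if sym_src in raw.columns else out["gene_id"]
    )
    for fieldname in ("log2fc", "mean_expr", "p_value"):
        out[fieldname] = raw[cmap.get(fieldname, fieldname)].map(_parse_float)
    padj_src = cmap.get("p_adj", "p_adj")
    out["p_adj"] = (
        raw[padj_src].map(_parse_float) if padj_src in raw.columns else np.nan
    )

    bad = (
        out["log2fc"].isna()
        | ~np.isfinite(out["log2fc"].to_numpy(float))
        | out["mean_expr"].isna()
        | (out["mean_expr"] < 0)
        | out["p_value"].isna()
        | (out["p_value"] < 0)
        | (out["p_value"] > 1)
    )
    if bad.any():
        # +2: header line plus 1-based numbering of the source file
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        log.warning("%s: rejected %d unparseable/out-of-range rows at lines %s",
                    path, len(rows), rows[:20])
        out = out[~bad]

    label = comparison_label if comparison_label is not None else path.stem
    return DEGTable(label, out.reset_index(drop=True))


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    """Write a DEG table as TSV with lossless float formatting."""
    table.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members per line)."""
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields (>= 3 required)"
                )
            name, desc, *members = fields
            sets.append(GeneSet(name, desc, frozenset(m for m in members if m)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def write_scorecards(
    cards: Sequence,  # Sequence[ClusterScoreCard]; kept loose to avoid a cycle
    path: str | Path,
    config: AnalysisConfig | None = None,
    metadata: Mapping | None = None,
) -> None:
    """Write cluster scorecards as a TSV sorted by final rank.

    A JSON sidecar ``<path>.meta.json`` records the configuration, the seed
    and any extra metadata so identical inputs reproduce identical bytes.
    """
    if not cards:
        raise ParameterError("write_scorecards: no cards to write")
    rows = [c.as_row() for c in cards]
    frame = pd.DataFrame(rows).sort_values("final_rank", kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "config": dataclasses.asdict(config) if config is not None else None,
        "metadata": dict(metadata) if metadata is not None else {},
    }
    with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=2)
        fh.write("\n")
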