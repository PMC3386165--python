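"""Screen, plate and prior-network I/O plus plate normalisation.

A screen is a genes x (condition x replicate) matrix of preprocessed
phenotype Z-scores.  Plate-level preprocessing follows the two-step scheme
used for reporter/DRAQ5 assays: the raw reporter signal B is divided by the
DRAQ5 cell-count proxy D, scaled so that the control wells of each plate
average exactly 1, and then standardised to per-plate Z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    ParseError,
    UsageError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlateMeasurement",
    "ScreenMatrix",
    "PriorNetwork",
    "read_screen",
    "write_screen",
    "read_plate_table",
    "normalize_plate",
    "zscore_plate",
    "read_prior",
    "write_network",
]


@dataclass(frozen=True)
class PlateMeasurement:
    """One well of a screening plate."""

    plate_id: str
    well_id: str
    raw_signal: float  # B: reporter intensity after background subtraction
    draq5: float  # D: DNA stain, proxies cell count; must be > 0
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.draq5 > 0:
            raise ValidationError(
                f"well {self.well_id} on plate {self.plate_id}: DRAQ5 must be > 0"
            )
        if self.raw_signal < 0:
            raise ValidationError(
                f"well {self.well_id} on plate {self.plate_id}: negative raw signal"
            )


class ScreenMatrix:
    """Genes x replicate-columns matrix of phenotype Z-scores.

    Columns are annotated with a (condition, replicate) pair; replicates of
    one condition form a block, which downstream permutation and bootstrap
    procedures treat as the experimental unit.
    """

    def __init__(
        self,
        genes: list[str],
        values: np.ndarray,
        replicate_map: list[tuple[str, int]],
    ) -> None:
        genes = [str(g) for g in genes]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("screen values must be a 2-D matrix")
        if len(genes) != values.shape[0]:
            raise ValidationError("gene list length does not match the value matrix")
        if len(replicate_map) != values.shape[1]:
            raise ValidationError("replicate_map length does not match the columns")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValidationError(f"duplicated gene identifiers: {dupes}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("screen contains non-finite values; impute upstream")
        self.genes = genes
        self.values = values
        self.replicate_map = [(str(c), int(r)) for c, r in replicate_map]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.replicate_map:
            if c not in seen:
                seen.append(c)
        return seen

    def condition_columns(self, condition: str) -> np.ndarray:
        """Column indices belonging to one condition block, in order."""
        idx = [i for i, (c, _) in enumerate(self.replicate_map) if c == condition]
        if not idx:
            raise ValidationError(f"unknown condition {condition!r}")
        return np.asarray(idx, dtype=int)

    def mean_phenotype(self, condition: str | None = None) -> np.ndarray:
        """Per-gene mean Z-score, over one condition block or over everything."""
        if condition is None:
            return self.values.mean(axis=1)
        return self.values[:, self.condition_columns(condition)].mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c}.{r}" for c, r in self.replicate_map]
        return pd.DataFrame(self.values, index=self.genes, columns=cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreenMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.replicate_map == other.replicate_map
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"ScreenMatrix({self.n_genes} genes, {len(self.conditions)} conditions, "
            f"{self.n_columns} columns)"
        )


@dataclass
class PriorNetwork:
    """Undirected set of gene pairs carrying prior evidence of interaction."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    source_label: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        canon = set()
        for g1, g2 in self.pairs:
            if g1 == g2:
                raise ValidationError(f"self-pair {g1!r} is not allowed in a prior")
            canon.add((g1, g2) if g1 < g2 else (g2, g1))
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        g1, g2 = pair
        key = (g1, g2) if g1 < g2 else (g2, g1)
        return key in self.pairs


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_screen(path: str, sep: str | None = None) -> ScreenMatrix:
    """Read a delimited screen table.

    First column: gene identifier.  Remaining column headers encode the
    replicate structure as ``condition.replicate`` (replicate an integer);
    a bare header is treated as condition with replicate 1.
    """
    sep = sep or _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: could not be read as a delimited table: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: needs a gene-identifier column plus >=2 numeric columns"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad[0] if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            ) from exc
    replicate_map: list[tuple[str, int]] = []
    for col in df.columns:
        name = str(col)
        cond, dot, rep = name.rpartition(".")
        if dot and rep.isdigit():
            replicate_map.append((cond, int(rep)))
        else:
            replicate_map.append((name, 1))
    return ScreenMatrix(list(df.index.astype(str)), values, replicate_map)


def write_screen(screen: ScreenMatrix, path: str, sep: str = "\t") -> None:
    screen.to_frame().to_csv(path, sep=sep, index_label="gene")


def read_plate_table(path: str, sep: str = "\t") -> list[PlateMeasurement]:
    """Read raw plate wells: columns plate_id, well_id, signal, draq5, is_control."""
    df = pd.read_csv(path, sep=sep)
    required = {"plate_id", "well_id", "signal", "draq5", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing plate columns {sorted(missing)}")
    wells = []
    for _, row in df.iterrows():
        wells.append(
            PlateMeasurement(
                plate_id=str(row["plate_id"]),
                well_id=str(row["well_id"]),
                raw_signal=float(row["signal"]),
                draq5=float(row["draq5"]),
                is_control=bool(row["is_control"]),
            )
        )
    return wells


def normalize_plate(wells: list[PlateMeasurement]) -> pd.DataFrame:
    """Per-cell signal scaled to the plate's control wells.

    M = (B/D) / mean over control wells of (B/D), computed independently
    within every plate, so controls average exactly 1 per plate.
    """
    if not wells:
        raise ValidationError("no wells supplied")
    df = pd.DataFrame(
        {
            "plate_id": [w.plate_id for w in wells],
            "well_id": [w.well_id for w in wells],
            "ratio": [w.raw_signal / w.draq5 for w in wells],
            "is_control": [w.is_control for w in wells],
        }
    )
    out = []
    for plate, grp in df.groupby("plate_id", sort=False):
        ctrl = grp.loc[grp["is_control"], "ratio"]
        if ctrl.empty:
            raise ConfigurationError(f"plate {plate!r} has no control wells")
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean <= 0:
            raise ValidationError(f"plate {plate!r}: control mean signal is not positive")
        sub = grp[["plate_id", "well_id"]].copy()
        sub["m"] = grp["ratio"] / ctrl_mean
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def zscore_plate(normalized: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardise normalised values to per-plate Z-scores.

    ddof=0 (population standard deviation) is the default convention;
    ddof=1 switches to the sample standard deviation.
    """
    required = {"plate_id", "well_id", "m"}
    if not required <= set(normalized.columns):
        raise ValidationError(f"normalized table must have columns {sorted(required)}")
    out = []
    for plate, grp in normalized.groupby("plate_id", sort=False):
        vals = grp["m"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValidationError(f"plate {plate!r}: need >=2 wells to standardise")
        sd = vals.std(ddof=ddof)
        if sd == 0:
            raise ValidationError(f"plate {plate!r}: zero variance across wells")
        sub = grp[["plate_id", "well_id"]].copy()
        sub["z"] = (vals - vals.mean()) / sd
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def read_prior(
    path: str,
    genes: list[str],
    sep: str | None = None,
    case_insensitive: bool = False,
    source_label: str | None = None,
) -> PriorNetwork:
    """Read a two-column pair list or SIF file, restricted to screened genes.

    SIF lines (``a <relation> b [c ...]``) are expanded to pairs of the
    first node with every node from the third token on.  Self-pairs are
    removed, duplicates merged, and pairs naming unscreened genes dropped
    (the drop count is logged and stored on the result).
    """
    lookup = {g.lower() if case_insensitive else g: g for g in genes}

    def resolve(name: str) -> str | None:
        return lookup.get(name.lower() if case_insensitive else name)

    pairs: set[tuple[str, str]] = set()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(sep) if sep else line.split()
            if len(tokens) == 2:
                raw_pairs = [(tokens[0], tokens[1])]
            elif len(tokens) >= 3:
                raw_pairs = [(tokens[0], t) for t in tokens[2:]]
            else:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {line!r}")
            for g1, g2 in raw_pairs:
                r1, r2 = resolve(g1), resolve(g2)
                if r1 is None or r2 is None:
                    dropped += 1
                    continue
                if r1 == r2:
                    continue
                pairs.add((r1, r2) if r1 < r2 else (r2, r1))
    if dropped:
        logger.info("read_prior: dropped %d pairs naming unscreened genes", dropped)
    return PriorNetwork(
        pairs=pairs, source_label=source_label or path, n_dropped=dropped
    )


def write_network(pan, path: str, format: str = "sif") -> None:  # noqa: A002
    """Serialise a posterior association network.

    Formats: ``sif`` (interaction types ``pos``/``neg``), ``graphml``
    (full attributes) and ``tsv`` (edge table gene1, gene2, sign, snr).
    """
    fmt = format.lower()
    graph = pan.graph if hasattr(pan, "graph") else pan
    if fmt == "sif":
        with open(path, "w") as fh:
            seen = set()
            for g1, g2, data in graph.edges(data=True):
                rel = "pos" if data.get("sign", "+") == "+" else "neg"
                fh.write(f"{g1}\t{rel}\t{g2}\n")
                seen.update((g1, g2))
            for node in graph.nodes:
                if node not in seen:
                    fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "tsv":
        rows = [
            {"gene1": g1, "gene2": g2, "sign": d.get("sign", "+"), "snr": d.get("snr")}
            for g1, g2, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["gene1", "gene2", "sign", "snr"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise UsageError(f"unknown network format {format!r}; use sif, graphml or tsv")
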