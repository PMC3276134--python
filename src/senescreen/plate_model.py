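"""Plates, layouts and culture time series for senescence screens.

A screen follows many replicate yeast cultures through serial passages,
recording an image-derived culture size for every culture at every passage.
Two designs are supported: a 96-well *liquid* design in which cultures are
diluted ~1:70 at each passage, and a 1536-position *solid* (pinned colony)
design in which the effective dilution is at most 16-fold.  This module
provides the domain types for both, deterministic layout generators, and
delimiter-separated readers/writers for culture-size tables of the kind
produced by colony-quantification tools such as Colonyzer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLATE_GRIDS",
    "WellPosition",
    "PlateLayout",
    "CultureSeries",
    "ScreenDataset",
    "GeneSet",
    "ValidationReport",
    "LayoutError",
    "TableFormatError",
    "DatasetValidationError",
    "build_liquid_layout",
    "build_solid_layout",
    "read_culture_table",
    "write_culture_table",
    "read_layout_table",
    "write_layout_table",
    "validate_dataset",
]

#: Supported plate formats mapped to their (rows, columns) grids.
PLATE_GRIDS: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}


class LayoutError(ValueError):
    """A plate layout request that cannot be satisfied."""


class TableFormatError(ValueError):
    """A culture or layout table that does not match the expected schema."""


class DatasetValidationError(ValueError):
    """A culture table whose contents violate dataset invariants."""


@dataclass(frozen=True, order=True)
class WellPosition:
    """A 1-based (row, col) position on a named plate."""

    plate_id: str
    row: int
    col: int

    def validate(self, plate_format: int) -> None:
        rows, cols = PLATE_GRIDS[plate_format]
        if not (1 <= self.row <= rows and 1 <= self.col <= cols):
            raise LayoutError(
                f"position ({self.row}, {self.col}) outside {plate_format}-format "
                f"grid {rows}x{cols} on plate {self.plate_id!r}"
            )


@dataclass
class PlateLayout:
    """Assignment of genotype labels to wells of a single plate.

    Positions absent from ``assignment`` are explicitly empty wells.
    """

    plate_id: str
    format: int
    assignment: dict[WellPosition, str]
    design: str = "liquid"

    def __post_init__(self) -> None:
        if self.format not in PLATE_GRIDS:
            raise LayoutError(f"unknown plate format {self.format}")
        if self.design not in ("liquid", "solid"):
            raise LayoutError(f"unknown design {self.design!r}")
        for pos in self.assignment:
            if pos.plate_id != self.plate_id:
                raise LayoutError(
                    f"position {pos} does not belong to plate {self.plate_id!r}"
                )
            pos.validate(self.format)

    @property
    def n_assigned(self) -> int:
        return len(self.assignment)

    def genotype_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label in self.assignment.values():
            counts[label] = counts.get(label, 0) + 1
        return counts


@dataclass
class CultureSeries:
    """One culture's size trajectory across passages 1..P."""

    position: WellPosition
    genotype: str
    sizes: np.ndarray  # shape (P,), non-negative

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.ndim != 1:
            raise ValueError("sizes must be a 1-D sequence")
        if np.any(self.sizes < 0):
            raise DatasetValidationError(
                f"negative culture size for {self.genotype!r} at {self.position}"
            )

    @property
    def passage_count(self) -> int:
        return int(self.sizes.shape[0])

    def is_sterile_from_start(self) -> bool:
        return bool(np.all(self.sizes == 0))


@dataclass
class ScreenDataset:
    """A validated collection of culture series sharing one passage count.

    ``scale`` records whether sizes are raw integrated intensities or have
    been variance-stabilized (see :mod:`senescreen.profile`).
    """

    cultures: list[CultureSeries]
    passage_count: int
    scale: str = "raw"
    design: str = "liquid"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "transformed"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.design not in ("liquid", "solid"):
            raise ValueError(f"unknown design {self.design!r}")
        for c in self.cultures:
            if c.passage_count != self.passage_count:
                raise DatasetValidationError(
                    f"culture at {c.position} has {c.passage_count} passages, "
                    f"dataset expects {self.passage_count}"
                )

    def genotypes(self) -> list[str]:
        """Distinct genotype labels in stable (sorted) order."""
        return sorted({c.genotype for c in self.cultures})

    def replicates(self, genotype: str) -> list[CultureSeries]:
        reps = [c for c in self.cultures if c.genotype == genotype]
        if not reps:
            raise KeyError(f"genotype {genotype!r} not present in dataset")
        return reps

    def size_matrix(self, genotype: str) -> np.ndarray:
        """Replicate-by-passage size matrix for one genotype."""
        return np.vstack([c.sizes for c in self.replicates(genotype)])

    def sizes_at_passage(self, passage: int) -> np.ndarray:
        """All individual culture sizes at one passage (1-based)."""
        if not 1 <= passage <= self.passage_count:
            raise ValueError(
                f"passage {passage} outside 1..{self.passage_count}"
            )
        return np.array([c.sizes[passage - 1] for c in self.cultures])

    def with_sizes(self, new_sizes: Iterable[np.ndarray], scale: str) -> "ScreenDataset":
        cultures = [
            replace(c, sizes=np.asarray(s, dtype=float))
            for c, s in zip(self.cultures, new_sizes, strict=True)
        ]
        return ScreenDataset(
            cultures=cultures,
            passage_count=self.passage_count,
            scale=scale,
            design=self.design,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per culture per passage."""
        records = []
        for c in self.cultures:
            for p in range(self.passage_count):
                records.append(
                    (
                        c.position.plate_id,
                        c.position.row,
                        c.position.col,
                        c.genotype,
                        p + 1,
                        c.sizes[p],
                    )
                )
        return pd.DataFrame(
            records, columns=["plate_id", "row", "col", "genotype", "passage", "size"]
        )


@dataclass
class GeneSet:
    """A named set of genotype labels (e.g. 'short telomere' genes)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, label: str) -> bool:
        return label in self.members


# ---------------------------------------------------------------------------
# layout generators
# ---------------------------------------------------------------------------

def _outer_frame_first_order(rows: int, cols: int) -> list[tuple[int, int]]:
    """All grid positions sorted outer frame first, then inward, row-major
    within each ring.  Deterministic; used to place control wells on the
    plate edge the way screen designs usually do."""
    def ring(r: int, c: int) -> int:
        return min(r - 1, c - 1, rows - r, cols - c)

    positions = [(r, c) for r in range(1, rows + 1) for c in range(1, cols + 1)]
    positions.sort(key=lambda rc: (ring(*rc), rc[0], rc[1]))
    return positions


def build_liquid_layout(
    genotypes_per_plate: Sequence[Sequence[str]],
    n_plates: int | None = None,
    controls_per_plate: int = 36,
    control_label: str = "his3",
) -> list[PlateLayout]:
    """Build 96-well liquid-design layouts.

    Each plate carries ``96 - controls_per_plate`` distinct query genotypes
    plus ``controls_per_plate`` independently generated control cultures of
    ``control_label``.  Controls occupy a fixed, deterministic set of wells
    (outer frame filled first); query genotypes fill the remaining wells in
    row-major order, one well per genotype per plate.

    Parameters
    ----------
    genotypes_per_plate
        One list of query genotype labels per plate.
    n_plates
        Expected number of plates; defaults to ``len(genotypes_per_plate)``
        and is checked against it.
    """
    if n_plates is None:
        n_plates = len(genotypes_per_plate)
    if len(genotypes_per_plate) != n_plates:
        raise LayoutError(
            f"expected {n_plates} genotype lists, got {len(genotypes_per_plate)}"
        )
    rows, cols = PLATE_GRIDS[96]
    expected_queries = 96 - controls_per_plate
    frame_order = _outer_frame_first_order(rows, cols)
    control_cells = set(frame_order[:controls_per_plate])
    query_cells = [rc for rc in frame_order if rc not in control_cells]
    query_cells.sort()  # row-major fill for query genotypes

    layouts = []
    for i, plate_genotypes in enumerate(genotypes_per_plate, start=1):
        plate_genotypes = list(plate_genotypes)
        if len(plate_genotypes) != expected_queries:
            raise LayoutError(
                f"plate {i}: expected {expected_queries} query genotypes "
                f"({96} wells minus {controls_per_plate} controls), "
                f"got {len(plate_genotypes)}"
            )
        if len(set(plate_genotypes)) != len(plate_genotypes):
            raise LayoutError(f"plate {i}: duplicate query genotype labels")
        plate_id = f"L{i:02d}"
        assignment: dict[WellPosition, str] = {}
        for r, c in sorted(control_cells):
            assignment[WellPosition(plate_id, r, c)] = control_label
        for (r, c), label in zip(query_cells, plate_genotypes, strict=True):
            assignment[WellPosition(plate_id, r, c)] = label
        layouts.append(
            PlateLayout(plate_id=plate_id, format=96, assignment=assignment, design="liquid")
        )
    return layouts


def build_solid_layout(
    genotype_list: Sequence[str],
    replicate_scheme: Mapping[str, int] | None = None,
    control_label: str | None = "his3",
    default_replicates: int = 8,
    control_replicates: int = 144,
) -> list[PlateLayout]:
    """Build 1536-position solid-design layouts.

    Every genotype receives ``replicate_scheme[genotype]`` positions
    (default ``default_replicates``; the control label defaults to
    ``control_replicates``; pass ``control_label=None`` for no implicit
    control).  Positions are filled in row-major order and overflow onto
    additional plates as needed.
    """
    rows, cols = PLATE_GRIDS[1536]
    capacity = rows * cols
    scheme: dict[str, int] = {}
    for g in genotype_list:
        scheme[g] = default_replicates
    if control_label is not None:
        scheme[control_label] = control_replicates
    if replicate_scheme:
        scheme.update(replicate_scheme)
    for g, n in scheme.items():
        if n <= 0:
            raise LayoutError(f"replicate count for {g!r} must be positive, got {n}")

    # stable fill order: listed genotypes first (in given order), then any
    # scheme-only extras sorted
    order = list(dict.fromkeys(genotype_list))
    if control_label is not None and control_label not in order:
        order.append(control_label)
    for g in sorted(scheme):
        if g not in order:
            order.append(g)

    layouts: list[PlateLayout] = []
    assignment: dict[WellPosition, str] = {}
    plate_no, idx = 1, 0

    def flush() -> None:
        nonlocal assignment, plate_no
        if assignment:
            layouts.append(
                PlateLayout(
                    plate_id=f"S{plate_no:02d}", format=1536,
                    assignment=assignment, design="solid",
                )
            )
            plate_no += 1
            assignment = {}

    for g in order:
        for _ in range(scheme[g]):
            if idx == capacity:
                flush()
                idx = 0
            r, c = divmod(idx, cols)
            assignment[WellPosition(f"S{plate_no:02d}", r + 1, c + 1)] = g
            idx += 1
    flush()
    return layouts


# ---------------------------------------------------------------------------
# tabular i/o
# ---------------------------------------------------------------------------

_CULTURE_COLUMNS = ["plate_id", "row", "col", "genotype", "passage", "size"]


def write_culture_table(dataset: ScreenDataset, path) -> None:
    """Write a dataset as a tab-separated culture table.

    The first line is a comment header carrying the scale, design and
    passage count.  Sizes are written at full precision (shortest decimal
    representation that round-trips the float exactly), so write-then-read
    is bit-exact on the size column.
    """
    with open(path, "w") as fh:
        fh.write(
            f"#scale={dataset.scale} #design={dataset.design} "
            f"#passages={dataset.passage_count}\n"
        )
        fh.write("\t".join(_CULTURE_COLUMNS) + "\n")
        for c in dataset.cultures:
            pos = c.position
            for p in range(dataset.passage_count):
                fh.write(
                    f"{pos.plate_id}\t{pos.row}\t{pos.col}\t{c.genotype}\t"
                    f"{p + 1}\t{float(c.sizes[p])!r}\n"
                )


def read_culture_table(path) -> ScreenDataset:
    """Read a culture table written by :func:`write_culture_table` (or any
    delimiter-separated table with the same columns).

    Raises
    ------
    DatasetValidationError
        If a culture's passages do not form a complete 1..P range, a size
        is negative, or the table is empty.
    """
    with open(path) as fh:
        first = fh.readline()
        meta = {"scale": "raw", "design": "liquid", "passages": None}
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.lstrip("#").split("=", 1)
                    if k in meta:
                        meta[k] = v
            body = fh.read()
        else:
            body = first + fh.read()
    if not body.strip():
        raise DatasetValidationError("empty culture table")
    sep = "\t" if "\t" in body.splitlines()[0] else ","
    df = pd.read_csv(
        io.StringIO(body), sep=sep, dtype={"plate_id": str, "genotype": str},
        float_precision="round_trip",  # bit-exact on the size column
    )
    missing = set(_CULTURE_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"culture table missing columns: {sorted(missing)}")
    if df.empty:
        raise DatasetValidationError("empty culture table")
    if (df["size"] < 0).any():
        bad = df.loc[df["size"] < 0].iloc[0]
        raise DatasetValidationError(
            f"negative size for {bad['genotype']!r} at plate {bad['plate_id']} "
            f"({bad['row']},{bad['col']}) passage {bad['passage']}"
        )

    declared_p = int(meta["passages"]) if meta["passages"] else int(df["passage"].max())

    cultures = []
    keys = ["plate_id", "row", "col", "genotype"]
    for (plate_id, row, col, genotype), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("passage")
        passages = grp["passage"].to_numpy()
        if not np.array_equal(passages, np.arange(1, declared_p + 1)):
            raise DatasetValidationError(
                f"culture {genotype!r} at plate {plate_id} ({row},{col}) has "
                f"passages {passages.tolist()}, expected complete 1..{declared_p}"
            )
        cultures.append(
            CultureSeries(
                position=WellPosition(str(plate_id), int(row), int(col)),
                genotype=str(genotype),
                sizes=grp["size"].to_numpy(dtype=float),
            )
        )
    return ScreenDataset(
        cultures=cultures,
        passage_count=declared_p,
        scale=meta["scale"],
        design=meta["design"],
    )


def write_layout_table(layouts: Iterable[PlateLayout], path) -> None:
    """Write plate layouts as a tab-separated table (plate_id,row,col,genotype)."""
    with open(path, "w") as fh:
        fh.write("plate_id\trow\tcol\tgenotype\n")
        for layout in layouts:
            for pos in sorted(layout.assignment):
                fh.write(f"{pos.plate_id}\t{pos.row}\t{pos.col}\t{layout.assignment[pos]}\n")


def read_layout_table(path, format: int, design: str = "liquid") -> list[PlateLayout]:
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "genotype": str})
    layouts = []
    for plate_id, grp in df.groupby("plate_id", sort=True):
        assignment = {
            WellPosition(str(plate_id), int(r.row), int(r.col)): str(r.genotype)
            for r in grp.itertuples()
        }
        layouts.append(PlateLayout(str(plate_id), format, assignment, design))
    return layouts


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Structured summary of a dataset's replicate structure and health."""

    n_cultures: int
    passage_count: int
    replicate_counts: dict[str, int]
    sterile_from_start: int
    below_minimum: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.replicate_counts.items()),
            columns=["genotype", "n_repeats"],
        )


def validate_dataset(dataset: ScreenDataset, min_replicates: int = 2) -> ValidationReport:
    """Summarize per-genotype replicate counts, passage completeness and
    sterile-from-start cultures.  Never raises; returns a report."""
    counts: dict[str, int] = {}
    sterile = 0
    for c in dataset.cultures:
        counts[c.genotype] = counts.get(c.genotype, 0) + 1
        if c.is_sterile_from_start():
            sterile += 1
    below = sorted(g for g, n in counts.items() if n < min_replicates)
    return ValidationReport(
        n_cultures=len(dataset.cultures),
        passage_count=dataset.passage_count,
        replicate_counts=counts,
        sterile_from_start=sterile,
        below_minimum=below,
    )
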