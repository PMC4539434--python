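"""Reading, normalizing and rescaling per-base coverage profiles.

Raw input is either a long TSV (gene_id, sample_id, position, count) or a
per-sample bedGraph.  Counts are scaled by a per-sample factor, shifted by
one and log-transformed so that zero counts map to exactly zero, and gene
coordinates are mapped affinely onto the canonical interval [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageProfile",
    "ExpressionCurve",
    "read_coverage",
    "read_labels",
    "normalize",
    "rescale_positions",
    "default_scale_factors",
    "write_curves",
    "read_curves",
]

DOMAIN = (0.0, 100.0)


@dataclass
class CoverageProfile:
    """Raw per-base read counts for one gene in one sample.

    ``positions`` are 1-based inclusive genomic coordinates, strictly
    increasing; ``counts`` are the non-negative read counts at each.
    """

    gene_id: str
    sample_id: str
    positions: np.ndarray
    counts: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.positions.shape != self.counts.shape:
            raise ValueError("positions and counts must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError(
                f"positions must be strictly increasing for "
                f"({self.gene_id}, {self.sample_id})"
            )
        if np.any(self.counts < 0):
            raise ValueError(
                f"negative count for ({self.gene_id}, {self.sample_id})"
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExpressionCurve:
    """Normalized log-expression values on the canonical [0, 100] scale."""

    gene_id: str
    sample_id: str
    t: np.ndarray
    y: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")
        if self.t.size < 4:
            raise ValueError("an expression curve needs at least 4 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not (
            math.isclose(self.t[0], DOMAIN[0], abs_tol=1e-6)
            and math.isclose(self.t[-1], DOMAIN[1], abs_tol=1e-6)
        ):
            raise ValueError(
                f"curve must span [{DOMAIN[0]:g}, {DOMAIN[1]:g}] after "
                f"rescaling; got [{self.t[0]:g}, {self.t[-1]:g}]"
            )
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")


# ---------------------------------------------------------------------------
# input parsing


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample_id -> group.

    A header line ``sample_id<TAB>group`` is accepted and skipped.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns (sample_id, group), "
                    f"got {len(fields)}: {line!r}"
                )
            if lineno == 1 and fields[0].lower() == "sample_id":
                continue
            labels[fields[0]] = fields[1]
    return labels


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def read_coverage(
    path: str | Path,
    labels_path: str | Path | None = None,
) -> list[CoverageProfile]:
    """Read per-base coverage into one :class:`CoverageProfile` per (gene, sample).

    Two formats are auto-detected:

    * long TSV with header ``gene_id  sample_id  position  count``
      (positions 1-based inclusive);
    * bedGraph ``chrom  start  end  count`` (0-based half-open intervals,
      expanded to per-base 1-based positions).  The chromosome field is used
      as the gene id and the file stem as the sample id.

    Negative counts, duplicate (gene, sample, position) records and coverage
    samples absent from the labels file are hard errors naming the offending
    line.  Unsorted input is sorted.
    """
    path = Path(path)
    labels = read_labels(labels_path) if labels_path is not None else None

    records: dict[tuple[str, str], dict[int, int]] = {}
    header_seen = False
    bedgraph = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            if not header_seen and not bedgraph:
                if fields[0].lower() == "gene_id":
                    header_seen = True
                    continue
                # no header: bedGraph iff columns 2 and 3 parse as integers
                bedgraph = _is_int(fields[1]) and _is_int(fields[2])
                if not bedgraph:
                    raise ValueError(
                        f"{path}:{lineno}: cannot detect format; long TSV "
                        "needs a 'gene_id sample_id position count' header"
                    )
            if bedgraph:
                gene, start, end, count = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                )
                sample = path.stem
                if end <= start:
                    raise ValueError(
                        f"{path}:{lineno}: empty bedGraph interval: {line!r}"
                    )
                positions = range(start + 1, end + 1)  # 0-based half-open -> 1-based
            else:
                gene, sample = fields[0], fields[1]
                if not _is_int(fields[2]):
                    raise ValueError(
                        f"{path}:{lineno}: non-integer position {fields[2]!r}"
                    )
                positions = [int(fields[2])]
                count = fields[3]
            if not _is_int(count):
                raise ValueError(f"{path}:{lineno}: non-integer count {count!r}")
            count = int(count)
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count: {line!r}")
            per_pos = records.setdefault((gene, sample), {})
            for pos in positions:
                if pos in per_pos:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate record for "
                        f"({gene}, {sample}, position {pos})"
                    )
                per_pos[pos] = count

    profiles = []
    for (gene, sample), per_pos in records.items():
        if labels is not None and sample not in labels:
            raise ValueError(
                f"sample {sample!r} in {path} is missing from the labels file"
            )
        positions = np.array(sorted(per_pos), dtype=np.int64)
        counts = np.array([per_pos[p] for p in positions], dtype=np.int64)
        profiles.append(
            CoverageProfile(
                gene_id=gene,
                sample_id=sample,
                positions=positions,
                counts=counts,
                group=labels.get(sample) if labels is not None else None,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# normalization


def rescale_positions(
    positions: np.ndarray, a: float, b: float
) -> np.ndarray:
    """Affinely map coordinates in ``[a, b]`` onto [0, 100]."""
    if not b > a:
        raise ValueError(f"need b > a, got a={a}, b={b}")
    positions = np.asarray(positions, dtype=float)
    if positions.size and (positions.min() < a or positions.max() > b):
        raise ValueError("positions fall outside the gene interval [a, b]")
    return 100.0 * (positions - a) / (b - a)


def normalize(
    profile: CoverageProfile,
    scale_factor: float,
    interval: tuple[int, int] | None = None,
) -> ExpressionCurve:
    """Turn raw counts into a normalized log-expression curve.

    ``y = log(count / scale_factor + 1)`` (natural log), so positions with
    zero counts map to exactly zero.  Positions are rescaled onto [0, 100]
    over the gene interval; when ``interval=(a, b)`` is given explicitly,
    unobserved positions inside it are filled with count 0.
    """
    if not scale_factor > 0:
        raise ValueError(f"scale_factor must be positive, got {scale_factor}")
    if interval is not None:
        a, b = int(interval[0]), int(interval[1])
        if not b > a:
            raise ValueError(f"gene interval must satisfy b > a, got ({a}, {b})")
        positions = np.arange(a, b + 1, dtype=np.int64)
        counts = np.zeros(positions.size)
        idx = np.searchsorted(positions, profile.positions)
        counts[idx] = profile.counts
    else:
        a, b = int(profile.positions[0]), int(profile.positions[-1])
        positions = profile.positions
        counts = profile.counts.astype(float)
    t = rescale_positions(positions, a, b)
    y = np.log1p(counts / scale_factor)
    return ExpressionCurve(
        gene_id=profile.gene_id,
        sample_id=profile.sample_id,
        t=t,
        y=y,
        group=profile.group,
    )


def default_scale_factors(
    profiles: Iterable[CoverageProfile],
) -> dict[str, float]:
    """Per-sample factors: total mapped reads / median of totals, so O(1)."""
    totals: dict[str, int] = {}
    for p in profiles:
        totals[p.sample_id] = totals.get(p.sample_id, 0) + p.total
    med = float(np.median(list(totals.values())))
    if med <= 0:
        raise ValueError("all samples have zero total counts")
    return {s: tot / med for s, tot in totals.items()}


# ---------------------------------------------------------------------------
# curve TSV round trip


def write_curves(curves: Sequence[ExpressionCurve], path: str | Path) -> None:
    """Write curves as a long TSV; floats use 17 significant digits so the
    round trip through :func:`read_curves` is bit-exact."""
    with open(path, "w") as fh:
        fh.write("gene_id\tsample_id\tgroup\tt\ty\n")
        for c in curves:
            group = c.group if c.group is not None else ""
            for tj, yj in zip(c.t, c.y):
                fh.write(f"{c.gene_id}\t{c.sample_id}\t{group}\t{tj:.17g}\t{yj:.17g}\n")


def read_curves(path: str | Path) -> list[ExpressionCurve]:
    df = pd.read_csv(
        path,
        sep="\t",
        keep_default_na=False,
        dtype={"group": str},
        float_precision="round_trip",
    )
    required = {"gene_id", "sample_id", "group", "t", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    curves = []
    for (gene, sample), sub in df.groupby(["gene_id", "sample_id"], sort=False):
        group = sub["group"].iloc[0]
        curves.append(
            ExpressionCurve(
                gene_id=str(gene),
                sample_id=str(sample),
                t=sub["t"].to_numpy(),
                y=sub["y"].to_numpy(),
                group=group if group != "" else None,
            )
        )
    return curves
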