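"""Marker maps and near-isogenic-line (NIL) introgression genotypes.

A NIL panel is genotyped at an ordered set of physical markers on one
chromosome.  Each line carries a single homozygous donor (SC) segment in the
recurrent-parent (PS) background, so every marker call is SC, PS or missing.
The interval between two adjacent markers is a *bin*: the atomic unit of
substitution mapping.  A bin's state for a line is fully determined by the
two flanking calls -- SC or PS when they agree, UNCERTAIN when they disagree
(a recombination breakpoint lies somewhere inside) or when either is missing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence


class GenotypeCall(str, enum.Enum):
    """Homozygous marker call: donor (SC), recurrent parent (PS), or missing."""

    SC = "SC"
    PS = "PS"
    MISSING = "NA"


class BinState(str, enum.Enum):
    SC = "SC"
    PS = "PS"
    UNCERTAIN = "UNCERTAIN"


class ClimactericClass(str, enum.Enum):
    NC = "NC"
    LC_MC = "LC_MC"


@dataclass(frozen=True)
class Marker:
    name: str
    chrom: str
    pos_bp: int

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.name}: pos_bp must be >= 1")


@dataclass(frozen=True)
class Bin:
    """Interval between two adjacent markers, 1-based inclusive coordinates."""

    left_marker: str
    right_marker: str
    left_pos: int
    right_pos: int
    index: int

    def __post_init__(self) -> None:
        if self.left_pos >= self.right_pos:
            raise ValueError("bin must have left_pos < right_pos")


@dataclass(frozen=True)
class RegionOfInterest:
    """A named physical interval, e.g. the climacteric QTL region ETHQB3.5."""

    name: str
    left_pos: int
    right_pos: int

    def __post_init__(self) -> None:
        if self.left_pos >= self.right_pos:
            raise ValueError("ROI must have left_pos < right_pos")


@dataclass(frozen=True)
class SCSegment:
    """Extent of one donor introgression of a line.

    ``certain_interval`` spans the outermost markers with SC calls;
    ``maximal_interval`` extends through flanking UNCERTAIN bins to the
    nearest PS-called marker (or the map end).
    """

    line_name: str
    certain_interval: tuple[int, int]
    maximal_interval: tuple[int, int]

    def __post_init__(self) -> None:
        (cl, cr), (ml, mr) = self.certain_interval, self.maximal_interval
        if not (ml <= cl <= cr <= mr):
            raise ValueError("certain_interval must lie within maximal_interval")


@dataclass
class LineGenotype:
    line_name: str
    calls: dict[str, GenotypeCall]
    climacteric_class: ClimactericClass = ClimactericClass.NC
    n_replicates: int = 1
    lenient: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.calls = {m: GenotypeCall(c) for m, c in self.calls.items()}

    def call(self, marker: str) -> GenotypeCall:
        try:
            return self.calls[marker]
        except KeyError:
            raise KeyError(
                f"line {self.line_name}: no call for marker {marker!r}"
            ) from None


def load_marker_map(rows: Iterable[tuple[str, str, int | str]]) -> list[Marker]:
    """Build an ordered marker list from (name, chrom, pos) rows.

    Rows must already be in map order; positions must be strictly increasing
    positive integers and names unique.
    """
    markers: list[Marker] = []
    seen: set[str] = set()
    for name, chrom, pos in rows:
        try:
            pos_int = int(pos)
        except (TypeError, ValueError):
            raise ValueError(f"marker {name}: non-integer position {pos!r}") from None
        if str(pos) != str(pos_int):
            raise ValueError(f"marker {name}: non-integer position {pos!r}")
        if name in seen:
            raise ValueError(f"duplicate marker name {name!r}")
        if markers and pos_int <= markers[-1].pos_bp:
            raise ValueError(
                f"marker {name}: position {pos_int} not ascending "
                f"(previous {markers[-1].name} at {markers[-1].pos_bp})"
            )
        seen.add(name)
        markers.append(Marker(name=name, chrom=chrom, pos_bp=pos_int))
    if not markers:
        raise ValueError("empty marker table")
    return markers


def derive_bins(markers: Sequence[Marker]) -> list[Bin]:
    """Tile the genotyped interval into the m-1 inter-marker bins."""
    if len(markers) < 2:
        raise ValueError("need at least 2 markers to derive bins")
    return [
        Bin(
            left_marker=a.name,
            right_marker=b.name,
            left_pos=a.pos_bp,
            right_pos=b.pos_bp,
            index=i,
        )
        for i, (a, b) in enumerate(zip(markers, markers[1:]))
    ]


def bin_state(line: LineGenotype, b: Bin) -> BinState:
    """State of a bin for a line, a pure function of the two flanking calls."""
    left, right = line.call(b.left_marker), line.call(b.right_marker)
    if left == right == GenotypeCall.SC:
        return BinState.SC
    if left == right == GenotypeCall.PS:
        return BinState.PS
    return BinState.UNCERTAIN


@dataclass
class IntrogressionMap:
    """An ordered marker map plus the genotyped NIL panel on it."""

    markers: list[Marker]
    lines: dict[str, LineGenotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # re-validate ordering invariants on construction
        self.markers = load_marker_map(
            [(m.name, m.chrom, m.pos_bp) for m in self.markers]
        )
        for line in self.lines.values():
            self._check_line(line)
        self._bins = derive_bins(self.markers) if len(self.markers) >= 2 else []
        self._marker_by_name = {m.name: m for m in self.markers}

    def _check_line(self, line: LineGenotype) -> None:
        missing = [m.name for m in self.markers if m.name not in line.calls]
        if missing:
            raise ValueError(
                f"line {line.line_name}: no calls for markers {missing}"
            )

    @property
    def bins(self) -> list[Bin]:
        return list(self._bins)

    @property
    def extent(self) -> tuple[int, int]:
        return self.markers[0].pos_bp, self.markers[-1].pos_bp

    def marker(self, name: str) -> Marker:
        try:
            return self._marker_by_name[name]
        except KeyError:
            raise KeyError(f"unknown marker {name!r}") from None

    def add_line(self, line: LineGenotype) -> None:
        self._check_line(line)
        self.lines[line.line_name] = line

    def bin_states(self, line_name: str) -> list[BinState]:
        line = self.lines[line_name]
        return [bin_state(line, b) for b in self._bins]

    def sc_segments(self, line_name: str) -> list[SCSegment]:
        """Donor segments of a line: maximal runs of SC marker calls.

        The certain interval spans the run's outermost SC markers (degenerate
        when a single marker is SC).  The maximal interval extends through
        adjacent UNCERTAIN bins -- i.e. past markers with missing calls and
        into recombination gaps -- to the nearest PS-called marker, clamped
        to the map extent.
        """
        line = self.lines[line_name]
        calls = [line.call(m.name) for m in self.markers]
        segments: list[SCSegment] = []
        i, n = 0, len(self.markers)
        while i < n:
            if calls[i] is not GenotypeCall.SC:
                i += 1
                continue
            j = i
            # run of SC calls possibly interrupted by MISSING (uncertain gap
            # interior to the run is still bridged only if SC resumes before
            # any PS call)
            k = j
            last_sc = j
            while k + 1 < n and calls[k + 1] is not GenotypeCall.PS:
                k += 1
                if calls[k] is GenotypeCall.SC:
                    last_sc = k
            certain = (self.markers[i].pos_bp, self.markers[last_sc].pos_bp)
            left_bound = self.markers[0].pos_bp
            for p in range(i - 1, -1, -1):
                if calls[p] is GenotypeCall.PS:
                    left_bound = self.markers[p].pos_bp
                    break
            right_bound = self.markers[-1].pos_bp
            for p in range(last_sc + 1, n):
                if calls[p] is GenotypeCall.PS:
                    right_bound = self.markers[p].pos_bp
                    break
            segments.append(
                SCSegment(
                    line_name=line_name,
                    certain_interval=certain,
                    maximal_interval=(left_bound, right_bound),
                )
            )
            i = k + 1
        return segments

    def interval_length_mb(self, left_marker: str, right_marker: str) -> float:
        """Physical distance between two markers in Mb, half-up to 2 decimals."""
        left, right = self.marker(left_marker), self.marker(right_marker)
        if left.pos_bp > right.pos_bp:
            raise ValueError(
                f"markers out of order: {left_marker} at {left.pos_bp} is "
                f"right of {right_marker} at {right.pos_bp}"
            )
        mb = Decimal(right.pos_bp - left.pos_bp) / Decimal(1_000_000)
        return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    def roi_from_markers(self, name: str, left_marker: str, right_marker: str) -> RegionOfInterest:
        return RegionOfInterest(
            name=name,
            left_pos=self.marker(left_marker).pos_bp,
            right_pos=self.marker(right_marker).pos_bp,
        )


def interval_to_bed(
    chrom: str, left_pos: int, right_pos: int, name: str = "."
) -> str:
    """One BED line for a 1-based closed interval (0-based half-open output)."""
    return f"{chrom}\t{left_pos - 1}\t{right_pos}\t{name}"


def segments_to_bed(imap: IntrogressionMap, which: str = "certain") -> str:
    """BED export of every line's SC segments (``certain`` or ``maximal``)."""
    if which not in ("certain", "maximal"):
        raise ValueError("which must be 'certain' or 'maximal'")
    chrom = imap.markers[0].chrom
    lines_out = []
    for line_name in imap.lines:
        for seg in imap.sc_segments(line_name):
            lo, hi = getattr(seg, f"{which}_interval")
            lines_out.append(interval_to_bed(chrom, lo, hi, line_name))
    return "\n".join(lines_out) + ("\n" if lines_out else "")
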