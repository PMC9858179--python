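"""Substitution mapping of single QTLs from NIL significance patterns.

The logic of substitution mapping: a line that differs significantly from
the recurrent parent must carry the causal donor allele inside its
introgression, and a line that does not differ must not (unless it is
flagged *lenient*, in which case its non-significant results are treated as
uninformative).  A candidate bin is therefore *consistent* with a trait's
significance pattern when every significant line covers it with donor (SC)
sequence and every informative non-significant line does not.  UNCERTAIN
bins (recombination gaps, missing calls) are compatible with either
constraint.

Calls distinguish bins that satisfy the constraints through certain calls
(the *strong core*) from bins that satisfy them only through uncertainty.
The reported interval is the marker-bounded hull of the whole consistent
run -- the maximal region the data cannot exclude -- while colocalization
with a region of interest and the left/right position class are judged on
the strong core, the region the data positively support.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .diffstats import SignificancePattern
from .genome_map import Bin, BinState, IntrogressionMap, RegionOfInterest, bin_state


class QTLStatus(str, enum.Enum):
    MAPPED = "MAPPED"
    NO_SIGNAL = "NO_SIGNAL"
    NOT_INTERPRETABLE = "NOT_INTERPRETABLE"


class PositionClass(str, enum.Enum):
    IN_ROI = "IN_ROI"
    LEFT_OF_ROI = "LEFT_OF_ROI"
    RIGHT_OF_ROI = "RIGHT_OF_ROI"
    NONE = "none"


class EthyleneLabel(enum.IntEnum):
    DEPENDENT = 1
    INDEPENDENT = -1
    UNCLASSIFIED = 0


@dataclass(frozen=True)
class MappingConfig:
    """Knobs of the mapping engine.

    ``fallback`` enables the dominant-direction retry for mixed-sign
    patterns (used for compound classes); ``lenient_lines`` lists lines
    whose non-significant entries impose no constraint.
    """

    fallback: bool = False
    lenient_lines: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "lenient_lines", frozenset(self.lenient_lines))


@dataclass(frozen=True)
class ConsistentRun:
    """A maximal contiguous run of pattern-consistent bins."""

    bin_indices: tuple[int, ...]
    core_indices: tuple[int, ...]        # strongly consistent subset
    interval: tuple[int, int]            # marker-bounded hull of the run
    markers: tuple[str, str]
    core_interval: tuple[int, int] | None  # hull of the strong core


@dataclass(frozen=True)
class QTLCall:
    trait: str
    status: QTLStatus
    direction: int = 0                     # +1 / -1, 0 when not mapped
    primary_interval: tuple[int, int] | None = None
    primary_markers: tuple[str, str] | None = None
    core_interval: tuple[int, int] | None = None
    alternate_intervals: tuple[tuple[int, int], ...] = ()
    colocalizes_roi: bool = False
    position_class: PositionClass = PositionClass.NONE
    scenario: str = "none"                 # i / ii / iii / none
    mode_used: str = "strict"              # strict / dominant_direction
    trait_class: str = ""

    def __post_init__(self) -> None:
        if self.status is QTLStatus.MAPPED:
            if self.direction not in (-1, 1) or self.primary_interval is None:
                raise ValueError("MAPPED call needs a direction and interval")


def _constraint_sets(
    pattern: SignificancePattern,
    config: MappingConfig,
    sign: int | None,
) -> tuple[set[str], set[str]]:
    """(lines that must carry SC, lines that must be PS) for one run mode.

    ``sign=None`` is the strict mode (all signed lines must carry);
    otherwise lines of the opposite sign are excluded from the constraint.
    """
    must_sc, must_ps = set(), set()
    for line, v in pattern.entries.items():
        if v == 0:
            if line not in config.lenient_lines:
                must_ps.add(line)
        elif sign is None or v == sign:
            must_sc.add(line)
    return must_sc, must_ps


def _bin_ok(state: BinState, want_sc: bool, strict: bool) -> bool:
    if strict:
        return state is (BinState.SC if want_sc else BinState.PS)
    return state is BinState.UNCERTAIN or state is (
        BinState.SC if want_sc else BinState.PS
    )


def consistent_bins(
    pattern: SignificancePattern,
    imap: IntrogressionMap,
    config: MappingConfig = MappingConfig(),
    sign: int | None = None,
) -> set[int]:
    """Indices of bins consistent with the pattern.

    In strict mode (``sign=None``) a mixed-sign pattern has no consistent
    bins -- one donor allele cannot move a trait in both directions.  In
    dominant-direction mode (``sign`` given) lines of the opposite sign are
    treated as excluded.  An all-zero pattern carries no evidence at all:
    every bin is vacuously consistent (callers treat it as NO_SIGNAL).
    """
    if pattern.is_null:
        return {b.index for b in imap.bins}
    if sign is None and len(pattern.signs) > 1:
        return set()
    must_sc, must_ps = _constraint_sets(pattern, config, sign)
    unknown = (must_sc | must_ps) - set(imap.lines)
    if unknown:
        raise KeyError(f"pattern lines not in the map: {sorted(unknown)}")
    out = set()
    for b in imap.bins:
        ok = all(
            _bin_ok(bin_state(imap.lines[ln], b), True, strict=False)
            for ln in must_sc
        ) and all(
            _bin_ok(bin_state(imap.lines[ln], b), False, strict=False)
            for ln in must_ps
        )
        if ok:
            out.add(b.index)
    return out


def _strong_bins(
    pattern: SignificancePattern,
    imap: IntrogressionMap,
    config: MappingConfig,
    sign: int | None,
    candidates: set[int],
) -> set[int]:
    must_sc, must_ps = _constraint_sets(pattern, config, sign)
    bins = {b.index: b for b in imap.bins}
    out = set()
    for i in candidates:
        b = bins[i]
        ok = all(
            _bin_ok(bin_state(imap.lines[ln], b), True, strict=True)
            for ln in must_sc
        ) and all(
            _bin_ok(bin_state(imap.lines[ln], b), False, strict=True)
            for ln in must_ps
        )
        if ok:
            out.add(i)
    return out


def _runs(indices: set[int], imap: IntrogressionMap,
          core: set[int]) -> list[ConsistentRun]:
    bins: list[Bin] = imap.bins
    runs: list[ConsistentRun] = []
    current: list[int] = []
    for b in bins:
        if b.index in indices:
            current.append(b.index)
        elif current:
            runs.append(_make_run(current, bins, core))
            current = []
    if current:
        runs.append(_make_run(current, bins, core))
    return runs


def _make_run(idx: list[int], bins: list[Bin], core: set[int]) -> ConsistentRun:
    first, last = bins[idx[0]], bins[idx[-1]]
    core_idx = tuple(i for i in idx if i in core)
    core_interval = None
    if core_idx:
        core_interval = (bins[core_idx[0]].left_pos, bins[core_idx[-1]].right_pos)
    return ConsistentRun(
        bin_indices=tuple(idx),
        core_indices=core_idx,
        interval=(first.left_pos, last.right_pos),
        markers=(first.left_marker, last.right_marker),
        core_interval=core_interval,
    )


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _judged_interval(run: ConsistentRun) -> tuple[int, int]:
    return run.core_interval if run.core_interval is not None else run.interval


def _colocalizes(run: ConsistentRun, roi: RegionOfInterest) -> bool:
    return _overlap_len(_judged_interval(run), (roi.left_pos, roi.right_pos)) > 0


def _position(run: ConsistentRun, roi: RegionOfInterest) -> PositionClass:
    lo, hi = _judged_interval(run)
    if _overlap_len((lo, hi), (roi.left_pos, roi.right_pos)) > 0:
        return PositionClass.IN_ROI
    if hi <= roi.left_pos:
        return PositionClass.LEFT_OF_ROI
    return PositionClass.RIGHT_OF_ROI


def _select_run(runs: list[ConsistentRun], roi: RegionOfInterest) -> ConsistentRun:
    """ROI-colocalizing run first, then most bins, then leftmost."""
    roi_runs = [r for r in runs if _colocalizes(r, roi)]
    pool = roi_runs or runs
    return max(pool, key=lambda r: (len(r.bin_indices), -r.bin_indices[0]))


def _mapped_call(
    trait: str,
    sign: int,
    runs: list[ConsistentRun],
    roi: RegionOfInterest,
    mode: str,
    trait_class: str,
) -> QTLCall:
    primary = _select_run(runs, roi)
    alternates = tuple(r.interval for r in runs if r is not primary)
    return QTLCall(
        trait=trait,
        status=QTLStatus.MAPPED,
        direction=sign,
        primary_interval=primary.interval,
        primary_markers=primary.markers,
        core_interval=primary.core_interval,
        alternate_intervals=alternates,
        colocalizes_roi=_colocalizes(primary, roi),
        position_class=_position(primary, roi),
        mode_used=mode,
        trait_class=trait_class,
    )


def map_single_qtl(
    pattern: SignificancePattern,
    imap: IntrogressionMap,
    roi: RegionOfInterest,
    config: MappingConfig = MappingConfig(),
    trait_class: str = "",
) -> QTLCall:
    """Call a single QTL for one trait from its significance pattern.

    Strict mode first; on failure (mixed signs or no consistent bin) and
    with ``config.fallback`` enabled, the dominant-direction mode is tried
    once per sign present.  If exactly one sign yields consistent bins the
    trait is mapped in that direction; if both do, the pattern carries
    two-QTL evidence and the trait is not interpretable under a single-QTL
    model.
    """
    if pattern.is_null:
        call = QTLCall(trait=pattern.trait, status=QTLStatus.NO_SIGNAL,
                       trait_class=trait_class)
        return call
    signs = pattern.signs
    if len(signs) == 1:
        sign = next(iter(signs))
        bins = consistent_bins(pattern, imap, config)
        if bins:
            core = _strong_bins(pattern, imap, config, None, bins)
            runs = _runs(bins, imap, core)
            call = _mapped_call(pattern.trait, sign, runs, roi, "strict",
                                trait_class)
            return replace(call, scenario=_scenario(call))
    if config.fallback:
        mapped: dict[int, list[ConsistentRun]] = {}
        for sign in sorted(signs):
            bins = consistent_bins(pattern, imap, config, sign=sign)
            if bins:
                core = _strong_bins(pattern, imap, config, sign, bins)
                mapped[sign] = _runs(bins, imap, core)
        if len(mapped) == 1:
            sign, runs = next(iter(mapped.items()))
            call = _mapped_call(pattern.trait, sign, runs, roi,
                                "dominant_direction", trait_class)
            return replace(call, scenario=_scenario(call))
    call = QTLCall(trait=pattern.trait, status=QTLStatus.NOT_INTERPRETABLE,
                   trait_class=trait_class)
    return replace(call, scenario=_scenario(call))


def _scenario(call: QTLCall) -> str:
    if call.status is QTLStatus.NO_SIGNAL:
        return "none"
    if call.status is QTLStatus.NOT_INTERPRETABLE:
        return "iii"
    return "i" if call.colocalizes_roi else "ii"


def scenario_class(call: QTLCall) -> str:
    """Mapping scenario: i = colocalizes with the ROI, ii = maps elsewhere,
    iii = not compatible with a single QTL."""
    if call.status is QTLStatus.NO_SIGNAL:
        raise ValueError("no-signal calls have no mapping scenario")
    return _scenario(call)


def classify_ethylene(call: QTLCall) -> EthyleneLabel:
    """Ethylene dependence: a mapped QTL colocalizing with the climacteric
    region is ethylene-dependent (+1); mapped elsewhere, independent (-1)."""
    if call.status is not QTLStatus.MAPPED:
        return EthyleneLabel.UNCLASSIFIED
    return EthyleneLabel.DEPENDENT if call.colocalizes_roi else EthyleneLabel.INDEPENDENT


@dataclass
class QTLSummary:
    n_traits: int = 0
    n_mapped: int = 0
    n_up: int = 0
    n_down: int = 0
    n_in_roi: int = 0
    n_in_roi_up: int = 0
    n_in_roi_down: int = 0
    n_outside: int = 0
    n_outside_left: int = 0
    n_outside_right: int = 0
    n_not_interpretable: int = 0
    n_no_signal: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def summarize_qtl_table(calls: list[QTLCall]) -> QTLSummary:
    s = QTLSummary(n_traits=len(calls))
    for c in calls:
        if c.status is QTLStatus.NO_SIGNAL:
            s.n_no_signal += 1
        elif c.status is QTLStatus.NOT_INTERPRETABLE:
            s.n_not_interpretable += 1
        else:
            s.n_mapped += 1
            if c.direction > 0:
                s.n_up += 1
            else:
                s.n_down += 1
            if c.colocalizes_roi:
                s.n_in_roi += 1
                if c.direction > 0:
                    s.n_in_roi_up += 1
                else:
                    s.n_in_roi_down += 1
            else:
                s.n_outside += 1
                if c.position_class is PositionClass.LEFT_OF_ROI:
                    s.n_outside_left += 1
                elif c.position_class is PositionClass.RIGHT_OF_ROI:
                    s.n_outside_right += 1
    return s
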