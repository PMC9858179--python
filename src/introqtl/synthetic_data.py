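"""Synthetic replicate-level abundance panels with planted QTL effects.

The generator emulates the structure of a NIL metabolite screen: per-line
replicates, log-normal measurement noise on the log2 scale, additive QTL
effects planted in genotype bins, shared latent factors producing
correlation blocks, detection-limit censoring to zero, and a final
per-sample compositional normalization.  For sample s of line L and trait t

    raw_st = 2 ** ( mu_t + beta_t * [state(L, b_t) = SC]
                    + gamma_t * f_{g_t, s} + eps_st ),

with eps ~ N(0, sigma_t^2) and per-sample latent factors f ~ N(0, 1).
Values below the q-quantile of the raw marginal are censored to zero
before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_map import BinState, IntrogressionMap
from .preprocess import AbundanceMatrix, normalize_relative
from .qtl_mapping import QTLCall, QTLStatus

DEFAULT_N_TRAITS = 161
DEFAULT_EFFECT = 2.0
DEFAULT_SIGMA = 0.5
DEFAULT_CENSOR_Q = 0.1


@dataclass(frozen=True)
class TraitSpec:
    name: str
    baseline: float                  # mu_t, log2 units
    qtl_bin: int | None = None       # planted bin index, None for null traits
    effect: float = 0.0              # beta_t, log2 units
    sign: int = 1
    group: int | None = None         # latent correlation block
    loading: float = 0.0             # gamma_t
    sigma: float = DEFAULT_SIGMA


@dataclass
class SimConfig:
    seed: int
    imap: IntrogressionMap
    traits: list[TraitSpec]
    censor_q: float = DEFAULT_CENSOR_Q

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_q < 0.5:
            raise ValueError("censoring quantile must be in [0, 0.5)")
        n_bins = len(self.imap.bins)
        for t in self.traits:
            if t.sigma <= 0:
                raise ValueError(f"trait {t.name}: sigma must be positive")
            if t.qtl_bin is not None and not 0 <= t.qtl_bin < n_bins:
                raise ValueError(
                    f"trait {t.name}: planted bin {t.qtl_bin} outside the map "
                    f"({n_bins} bins)"
                )


@dataclass
class SimTruth:
    traits: dict[str, TraitSpec]
    carrier: pd.DataFrame  # lines x traits, 1 where the line carries the QTL

    def planted(self) -> list[str]:
        return [n for n, t in self.traits.items() if t.qtl_bin is not None]

    def null(self) -> list[str]:
        return [n for n, t in self.traits.items() if t.qtl_bin is None]


def default_config(
    imap: IntrogressionMap,
    seed: int,
    n_traits: int = DEFAULT_N_TRAITS,
    qtl_fraction: float = 0.15,
    effect: float = DEFAULT_EFFECT,
    sigma: float = DEFAULT_SIGMA,
    n_groups: int = 5,
    loading: float = 1.0,
    censor_q: float = DEFAULT_CENSOR_Q,
    certain_bins_only: bool = True,
) -> SimConfig:
    """A study-like panel: a minority of traits carry one QTL planted in a
    random (by default breakpoint-free) bin, organised into latent blocks."""
    rng = np.random.default_rng([seed, 0xC0F])  # distinct from the data stream
    bins = imap.bins
    if certain_bins_only:
        candidate_bins = [
            b.index
            for b in bins
            if all(
                imap.bin_states(ln)[b.index] is not BinState.UNCERTAIN
                for ln in imap.lines
            )
        ]
    else:
        candidate_bins = [b.index for b in bins]
    if not candidate_bins:
        raise ValueError("no candidate bins to plant QTLs in")
    traits = []
    n_qtl = int(round(qtl_fraction * n_traits))
    for i in range(n_traits):
        has_qtl = i < n_qtl
        traits.append(
            TraitSpec(
                name=f"T{i + 1:03d}",
                baseline=float(rng.uniform(2.0, 8.0)),
                qtl_bin=int(rng.choice(candidate_bins)) if has_qtl else None,
                effect=effect if has_qtl else 0.0,
                sign=int(rng.choice([-1, 1])) if has_qtl else 1,
                group=int(rng.integers(n_groups)),
                loading=loading if rng.random() < 0.5 else 0.0,
                sigma=sigma,
            )
        )
    return SimConfig(seed=seed, imap=imap, traits=traits, censor_q=censor_q)


def recovery_config(
    imap: IntrogressionMap,
    seed: int,
    n_traits: int = 200,
    effect: float = DEFAULT_EFFECT,
    sigma: float = DEFAULT_SIGMA,
) -> SimConfig:
    """Panel for QTL parameter-recovery experiments.

    Isolates the planted-QTL signal: no latent correlation blocks and no
    detection-limit censoring, so recovery and false-map rates measure the
    screening + mapping chain itself rather than the generator's nuisance
    structure.  Effects are planted only in breakpoint-free bins (recovery
    against a known bin is only well defined where carrier status is
    certain).
    """
    return default_config(
        imap, seed=seed, n_traits=n_traits, qtl_fraction=0.15, effect=effect,
        sigma=sigma, loading=0.0, censor_q=0.0, certain_bins_only=True,
    )


def simulate_dataset(config: SimConfig) -> tuple[AbundanceMatrix, SimTruth]:
    """Draw one replicate-level dataset; bitwise reproducible from the seed."""
    rng = np.random.default_rng([config.seed, 0xD47A])
    imap = config.imap
    lines = list(imap.lines)
    states = {ln: imap.bin_states(ln) for ln in lines}
    sample_ids, sample_lines = [], []
    for ln in lines:
        for r in range(imap.lines[ln].n_replicates):
            sample_ids.append(f"{ln}_r{r + 1}")
            sample_lines.append(ln)
    n_samples, n_traits = len(sample_ids), len(config.traits)
    groups = sorted({t.group for t in config.traits if t.group is not None})
    factors = rng.standard_normal((n_samples, len(groups))) if groups else None
    gidx = {g: i for i, g in enumerate(groups)}

    log2_vals = np.empty((n_samples, n_traits))
    carrier = pd.DataFrame(0, index=lines, columns=[t.name for t in config.traits])
    for j, t in enumerate(config.traits):
        mu = np.full(n_samples, t.baseline)
        if t.qtl_bin is not None:
            for ln in lines:
                st = states[ln][t.qtl_bin]
                carries = st is BinState.SC
                carrier.loc[ln, t.name] = int(carries)
                if carries:
                    mask = np.array([s == ln for s in sample_lines])
                    mu[mask] += t.sign * t.effect
        if t.group is not None and t.loading:
            mu = mu + t.loading * factors[:, gidx[t.group]]
        log2_vals[:, j] = mu + t.sigma * rng.standard_normal(n_samples)

    raw = np.exp2(log2_vals)
    if config.censor_q > 0:
        lod = np.quantile(raw, config.censor_q)
        raw = np.where(raw < lod, 0.0, raw)
    matrix = AbundanceMatrix(
        values=pd.DataFrame(
            raw, index=sample_ids, columns=[t.name for t in config.traits]
        ),
        sample_line=pd.Series(sample_lines, index=sample_ids),
    )
    truth = SimTruth(traits={t.name: t for t in config.traits}, carrier=carrier)
    return normalize_relative(matrix), truth


@dataclass
class RecoveryMetrics:
    recovery: float          # planted traits mapped with the true bin inside
    direction_accuracy: float
    false_map_rate: float    # null traits called MAPPED
    n_planted: int = 0
    n_null: int = 0


def evaluate_recovery(calls: list[QTLCall], truth: SimTruth,
                      imap: IntrogressionMap) -> RecoveryMetrics:
    by_trait = {c.trait: c for c in calls}
    missing = set(truth.traits) - set(by_trait)
    if missing:
        raise ValueError(f"calls missing for traits: {sorted(missing)[:5]} ...")
    bins = imap.bins
    planted, null = truth.planted(), truth.null()
    n_recovered = n_correct_dir = n_false = 0
    for name in planted:
        spec, call = truth.traits[name], by_trait[name]
        if call.status is not QTLStatus.MAPPED:
            continue
        b = bins[spec.qtl_bin]
        lo, hi = call.primary_interval
        if lo <= b.left_pos and b.right_pos <= hi:
            n_recovered += 1
            if call.direction == spec.sign:
                n_correct_dir += 1
    for name in null:
        if by_trait[name].status is QTLStatus.MAPPED:
            n_false += 1
    return RecoveryMetrics(
        recovery=n_recovered / len(planted) if planted else float("nan"),
        direction_accuracy=(
            n_correct_dir / n_recovered if n_recovered else float("nan")
        ),
        false_map_rate=n_false / len(null) if null else float("nan"),
        n_planted=len(planted),
        n_null=len(null),
    )
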