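"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introqtl.diffstats import (
    SignificancePattern,
    anova_per_trait,
    attach_bh,
    dunnett_many_to_one,
    screen_traits,
    significance_patterns,
)
from introqtl.genome_map import (
    BinState,
    GenotypeCall,
    IntrogressionMap,
    LineGenotype,
    Marker,
    RegionOfInterest,
    bin_state,
)
from introqtl.io import load_fixture_bundle
from introqtl.preprocess import preprocess
from introqtl.qtl_mapping import MappingConfig, map_single_qtl
from introqtl.synthetic_data import evaluate_recovery, recovery_config, simulate_dataset


@pytest.fixture(scope="session")
def bundle():
    return load_fixture_bundle()


@pytest.fixture(scope="session")
def imap(bundle):
    return bundle.imap


@pytest.fixture(scope="session")
def roi(bundle):
    return bundle.roi


# ------------------------------------------------------------------ oracles

def bh_oracle(p):
    """Literal step-up definition of the Benjamini-Hochberg adjustment."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, n * p[i] / (rank + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def brute_consistent_bins(entries, imap, lenient=frozenset(), sign=None):
    """Exhaustive re-statement of the bin-consistency rule, clause by clause."""
    if all(v == 0 for v in entries.values()):  # no evidence: vacuously true
        return {b.index for b in imap.bins}
    if sign is None and len({v for v in entries.values() if v != 0}) > 1:
        return set()
    out = set()
    for b in imap.bins:
        ok = True
        for line_name, v in entries.items():
            state = bin_state(imap.lines[line_name], b)
            if v == 0:
                if line_name in lenient:
                    continue
                if state not in (BinState.PS, BinState.UNCERTAIN):
                    ok = False
            elif sign is not None and v != sign:
                continue  # excluded line in dominant-direction mode
            else:
                if state not in (BinState.SC, BinState.UNCERTAIN):
                    ok = False
        if ok:
            out.add(b.index)
    return out


def random_panel(rng, max_lines=6, max_markers=16):
    """A random marker map + genotype panel + pattern for oracle testing."""
    m = int(rng.integers(2, max_markers + 1))
    positions = np.cumsum(rng.integers(1, 10_000, size=m)) + 1
    markers = [Marker(f"M{i}", "chrN", int(p)) for i, p in enumerate(positions)]
    n_lines = int(rng.integers(1, max_lines + 1))
    lines = {}
    calls_pool = [GenotypeCall.SC, GenotypeCall.PS, GenotypeCall.MISSING]
    for j in range(n_lines):
        calls = {
            mk.name: calls_pool[int(rng.integers(3))] for mk in markers
        }
        lines[f"L{j}"] = LineGenotype(
            line_name=f"L{j}", calls=calls, n_replicates=2,
            lenient=bool(rng.random() < 0.25),
        )
    panel = IntrogressionMap(markers=markers, lines=lines)
    entries = {name: int(rng.integers(-1, 2)) for name in lines}
    lo = int(rng.integers(positions[0], positions[-1]))
    hi = int(rng.integers(lo + 1, positions[-1] + 2))
    roi = RegionOfInterest("roi", lo, hi)
    return panel, entries, roi


def pairwise_ward_cost(d, members_a, members_b, squared):
    """Ward merge criterion computed from the original distance matrix.

    Uses the centroid identity on (squared) distances; independent of the
    Lance-Williams recurrence used by the implementation.
    """
    q = d**2 if squared else d
    a, b = list(members_a), list(members_b)
    na, nb = len(a), len(b)
    cross = q[np.ix_(a, b)].sum() / (na * nb)
    within_a = q[np.ix_(a, a)].sum() / (2 * na * na)
    within_b = q[np.ix_(b, b)].sum() / (2 * nb * nb)
    sep = cross - within_a - within_b
    return (2.0 * na * nb / (na + nb)) * sep


def ward_oracle(d, squared):
    """Greedy Ward agglomeration recomputing the criterion from scratch at
    every step (lowest-pair tie-break), returning the merge sequence."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        ids = sorted(clusters)
        for ii, a in enumerate(ids):
            for b in ids[ii + 1:]:
                cost = pairwise_ward_cost(d, clusters[a], clusters[b], squared)
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, a, b)
        cost, a, b = best
        height = np.sqrt(cost) if squared else cost
        merges.append((a, b, height))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def adjusted_rand(labels_a, labels_b):
    """Pair-counting adjusted Rand index."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b).reindex(a.index)
    contingency = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(contingency.sum())
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


# ------------------------------------------------------- pipeline helper

def run_recovery(imap, roi, seed, n_traits=200, effect=2.0, sigma=0.5):
    """Full chain on one synthetic panel: preprocess, screen, Dunnett,
    substitution-map, and score against the planted truth."""
    config = recovery_config(imap, seed=seed, n_traits=n_traits,
                             effect=effect, sigma=sigma)
    abundance, truth = simulate_dataset(config)
    logm = preprocess(abundance)
    anova = attach_bh(anova_per_trait(logm.values, logm.sample_line))
    kept = set(screen_traits(anova))
    dunnett = dunnett_many_to_one(logm.values, logm.sample_line, control="PS")
    patterns = []
    for res, pat in zip(dunnett, significance_patterns(dunnett)):
        if res.trait not in kept:  # screened-out traits carry no signal
            pat = SignificancePattern(res.trait, {k: 0 for k in pat.entries})
        patterns.append(pat)
    calls = [map_single_qtl(p, imap, roi, MappingConfig()) for p in patterns]
    return evaluate_recovery(calls, truth, imap)
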