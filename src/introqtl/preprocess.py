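"""Abundance preprocessing: relative normalization, zero substitution, log2.

Trait values are chromatographic peak areas.  Each sample is first expressed
as percentages of its own total area (a compositional normalization), zeros
-- detection-limit censoring -- are replaced by the minimum non-zero value
observed anywhere in the matrix, and the result is log2-transformed for the
downstream linear-model statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: compound classes recognised in trait metadata
COMPOUND_CLASSES = (
    "ACE", "NAE", "ALD", "ALC", "KET", "ACD", "SDC", "TER", "AHA", "OTH", "NID",
)

SUM_TOL = 1e-6  # relative tolerance for the per-sample sums-to-100 invariant


@dataclass
class AbundanceMatrix:
    """Samples x traits relative abundances with sample->line bookkeeping.

    ``values`` is a DataFrame indexed by sample id with trait columns;
    ``sample_line`` maps each sample to its pedigree line; ``trait_meta``
    (optional) carries at least a ``class`` column per trait.
    """

    values: pd.DataFrame
    sample_line: pd.Series
    trait_meta: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        self.sample_line = self.sample_line.reindex(self.values.index)
        if self.sample_line.isna().any():
            bad = list(self.values.index[self.sample_line.isna()])
            raise ValueError(f"samples without line assignment: {bad}")
        if self.normalized:
            totals = self.values.sum(axis=1).to_numpy()
            if not np.allclose(totals, 100.0, rtol=SUM_TOL):
                raise ValueError("normalized matrix rows must sum to 100")


@dataclass
class LogMatrix:
    """log2 of a zero-substituted abundance matrix."""

    values: pd.DataFrame
    sample_line: pd.Series
    substitution_constant: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("log matrix must be finite everywhere")


def normalize_relative(raw: AbundanceMatrix) -> AbundanceMatrix:
    """Express every sample as percentages of its own total area."""
    totals = raw.values.sum(axis=1)
    zero_rows = totals[totals <= 0]
    if len(zero_rows):
        raise ValueError(
            f"samples with all-zero areas cannot be normalized: {list(zero_rows.index)}"
        )
    values = raw.values.div(totals, axis=0) * 100.0
    return AbundanceMatrix(
        values=values,
        sample_line=raw.sample_line,
        trait_meta=raw.trait_meta,
        normalized=True,
    )


def substitute_zeros(matrix: pd.DataFrame, per_trait: bool = False) -> tuple[pd.DataFrame, float]:
    """Replace zeros by the minimum non-zero value of the whole matrix.

    Returns the substituted matrix and the constant used.  With
    ``per_trait=True`` each trait column uses its own minimum non-zero value
    instead (the returned constant is then the global one, for provenance);
    all-zero columns still fall back to the global constant.
    """
    arr = matrix.to_numpy(dtype=float)
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero matrix: no minimum non-zero value exists")
    global_min = float(nonzero.min())
    out = matrix.copy()
    if per_trait:
        for col in out.columns:
            col_vals = out[col].to_numpy(dtype=float)
            pos = col_vals[col_vals > 0]
            fill = float(pos.min()) if pos.size else global_min
            out[col] = np.where(col_vals == 0.0, fill, col_vals)
    else:
        out = out.mask(out == 0.0, global_min)
    return out, global_min


def log2_transform(matrix: pd.DataFrame, sample_line: pd.Series,
                   substitution_constant: float = float("nan")) -> LogMatrix:
    arr = matrix.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("log2 transform requires a strictly positive matrix "
                         "(substitute zeros first)")
    return LogMatrix(
        values=pd.DataFrame(
            np.log2(arr), index=matrix.index, columns=matrix.columns
        ),
        sample_line=sample_line,
        substitution_constant=substitution_constant,
    )


def preprocess(raw: AbundanceMatrix, per_trait_substitution: bool = False) -> LogMatrix:
    """Full chain: relative normalization -> zero substitution -> log2."""
    rel = raw if raw.normalized else normalize_relative(raw)
    filled, const = substitute_zeros(rel.values, per_trait=per_trait_substitution)
    return log2_transform(filled, rel.sample_line, const)


def class_totals(matrix: pd.DataFrame, trait_meta: pd.DataFrame,
                 classes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-sample totals of relative abundance by compound class.

    ``trait_meta`` must have a ``class`` entry for every trait column.
    ``classes`` fixes the output column order (and allows empty classes,
    reported as zero columns); by default the classes present are used.
    """
    missing = [t for t in matrix.columns if t not in trait_meta.index]
    if missing:
        raise ValueError(f"traits without class assignment: {missing}")
    assigned = trait_meta.loc[list(matrix.columns), "class"]
    unknown = sorted(set(assigned) - set(COMPOUND_CLASSES))
    if unknown:
        raise ValueError(f"unknown compound classes: {unknown}")
    cols = list(classes) if classes is not None else sorted(set(assigned))
    out = pd.DataFrame(0.0, index=matrix.index, columns=cols)
    for cls, group in matrix.T.groupby(assigned):
        if cls in out.columns:
            out[cls] = group.sum(axis=0)
    return out
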