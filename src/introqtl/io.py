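"""File formats, packaged fixtures, configuration and pipeline assembly.

Formats are plain text: TSV for maps, genotypes and result tables, CSV for
replicate-level abundances, BED for interval export, GraphML / edge lists
for the correlation network and Newick for dendrograms.

The packaged fixtures encode the printed study tables for a melon NIL
panel: the chromosome-3 marker map, per-line metadata, the screened-trait
significance patterns with their printed means, the per-trait QTL outcomes
used as ground truth, and the published correlation-network groups.  The
genotype matrix itself is a synthetic reconstruction (the source figure is
graphical): it is the unique-up-to-equivalence call matrix satisfying the
panel's published breakpoint constraints and reproducing every published
QTL call, and it is tagged as derived, not printed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .diffstats import SignificancePattern
from .genome_map import (
    ClimactericClass,
    GenotypeCall,
    IntrogressionMap,
    LineGenotype,
    RegionOfInterest,
    interval_to_bed,
    load_marker_map,
)
from .multivariate import Dendrogram, VOCGroup
from .preprocess import AbundanceMatrix
from .qtl_mapping import (
    MappingConfig,
    QTLCall,
    QTLStatus,
    classify_ethylene,
    map_single_qtl,
    summarize_qtl_table,
)

NIL_LINES = ("SC3-5-7", "SC3-5-8", "SC3-5-12", "SC3-5-13", "SC3-5-14")
ROI_NAME = "ETHQB3.5"
ROI_MARKERS = ("CMPSNP374", "AI_14-F04")


# ---------------------------------------------------------------- readers

def read_marker_map(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["marker", "chrom", "pos_bp"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: malformed marker header {list(df.columns)}, "
            f"expected {required}"
        )
    return load_marker_map(df[required].itertuples(index=False, name=None))


def read_genotypes(geno_path, meta_path) -> dict[str, LineGenotype]:
    """Genotype matrix (lines x markers, SC/PS/NA) plus the line sidecar."""
    geno = pd.read_csv(geno_path, sep="\t", dtype=str).set_index("line")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("line")
    markers = list(geno.columns)
    valid = {c.value for c in GenotypeCall}
    lines = {}
    for line, row in geno.iterrows():
        calls = {}
        for m in markers:
            val = row[m]
            if val not in valid:
                raise ValueError(
                    f"{geno_path}: line {line}, marker {m}: unknown genotype "
                    f"code {val!r}"
                )
            calls[m] = GenotypeCall(val)
        if line not in meta.index:
            raise ValueError(f"{meta_path}: no metadata for line {line}")
        lines[line] = LineGenotype(
            line_name=str(line),
            calls=calls,
            climacteric_class=ClimactericClass(meta.loc[line, "class"]),
            n_replicates=int(meta.loc[line, "n_replicates"]),
            lenient=bool(int(meta.loc[line, "lenient"])),
        )
    return lines


def read_abundance_csv(path) -> AbundanceMatrix:
    """Replicate-level abundances: sample id, line id, then trait columns."""
    df = pd.read_csv(path)
    if df.empty or df.shape[1] < 3:
        raise ValueError(
            f"{path}: expected sample, line and at least one trait column"
        )
    sample_col, line_col = df.columns[0], df.columns[1]
    df = df.set_index(sample_col)
    traits = df.columns[1:]
    try:
        values = df[traits].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance value ({exc})") from None
    return AbundanceMatrix(values=values, sample_line=df[line_col])


def read_pattern_tsv(path) -> list[SignificancePattern]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    line_cols = [c for c in df.columns if c.startswith("sig_")]
    if "trait" not in df.columns or not line_cols:
        raise ValueError(f"{path}: expected 'trait' plus sig_<line> columns")
    out = []
    for _, row in df.iterrows():
        entries = {c[len("sig_"):]: int(row[c]) for c in line_cols}
        out.append(SignificancePattern(str(row["trait"]), entries, source="encoded"))
    return out


def write_pattern_tsv(patterns: list[SignificancePattern], path) -> None:
    lines = sorted({ln for p in patterns for ln in p.entries})
    rows = [
        {"trait": p.trait, **{f"sig_{ln}": p.entries.get(ln, 0) for ln in lines}}
        for p in patterns
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- writers

def qtl_table(calls: list[QTLCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        lo, hi = c.primary_interval or (None, None)
        lm, rm = c.primary_markers or (None, None)
        rows.append(
            {
                "trait": c.trait,
                "class": c.trait_class,
                "status": c.status.value,
                "direction": c.direction,
                "left_marker": lm,
                "right_marker": rm,
                "left_pos": lo,
                "right_pos": hi,
                "colocalizes": int(c.colocalizes_roi),
                "position": c.position_class.value,
                "scenario": c.scenario,
                "ethylene_label": int(classify_ethylene(c)),
                "mode": c.mode_used,
            }
        )
    return pd.DataFrame(rows)


def write_qtl_tsv(calls: list[QTLCall], path) -> None:
    qtl_table(calls).to_csv(path, sep="\t", index=False)


def write_qtl_bed(calls: list[QTLCall], chrom: str, path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            if c.primary_interval:
                lo, hi = c.primary_interval
                fh.write(interval_to_bed(chrom, lo, hi, c.trait) + "\n")


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("trait_a\ttrait_b\tr\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['r']:.6g}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_newick(dend: Dendrogram, path) -> None:
    Path(path).write_text(dend.to_newick() + "\n")


def write_summary_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------- fixtures

def _fixture_path(name: str):
    return resources.files("introqtl.fixtures").joinpath(name)


@dataclass
class FixtureBundle:
    imap: IntrogressionMap
    roi: RegionOfInterest
    trait_patterns: list[SignificancePattern]   # 110 screened VOCs, by CAS id
    trait_table: pd.DataFrame                   # printed means and metadata
    class_patterns: list[SignificancePattern]   # 10 compound classes
    class_table: pd.DataFrame
    qtl_truth: pd.DataFrame                     # printed per-VOC QTL outcomes
    cna_groups: dict[str, list[str]]            # published groups G1..G5

    def __post_init__(self) -> None:
        if len(self.imap.markers) != 15:
            raise ValueError("fixture integrity: expected 15 markers")
        if len(self.trait_patterns) != 110:
            raise ValueError("fixture integrity: expected 110 trait patterns")
        if len(self.qtl_truth) != 44:
            raise ValueError("fixture integrity: expected 44 QTL truth rows")
        traits = {p.trait for p in self.trait_patterns}
        missing = set(self.qtl_truth["cas"]) - traits
        if missing:
            raise ValueError(
                f"fixture integrity: truth rows without patterns: {missing}"
            )


def _patterns_from_table(df: pd.DataFrame, key: str) -> list[SignificancePattern]:
    out = []
    for _, row in df.iterrows():
        entries = {nil: int(row[f"sig_{nil}"]) for nil in NIL_LINES}
        out.append(SignificancePattern(str(row[key]), entries, source="encoded"))
    return out


def load_fixture_bundle() -> FixtureBundle:
    markers = read_marker_map(_fixture_path("markers_chr3.tsv"))
    lines = read_genotypes(
        _fixture_path("genotypes.tsv"), _fixture_path("line_meta.tsv")
    )
    imap = IntrogressionMap(markers=markers, lines=lines)
    roi = imap.roi_from_markers(ROI_NAME, *ROI_MARKERS)
    t2 = pd.read_csv(_fixture_path("table2_patterns.tsv"), sep="\t", dtype=str)
    t1 = pd.read_csv(_fixture_path("table1_class_patterns.tsv"), sep="\t", dtype=str)
    truth = pd.read_csv(_fixture_path("table4_truth.tsv"), sep="\t")
    truth["cas"] = truth["cas"].astype(str)
    t5 = pd.read_csv(_fixture_path("table5_groups.tsv"), sep="\t", dtype=str)
    groups = {g: list(sub["cas"]) for g, sub in t5.groupby("group", sort=True)}
    return FixtureBundle(
        imap=imap,
        roi=roi,
        trait_patterns=_patterns_from_table(t2, "cas"),
        trait_table=t2,
        class_patterns=_patterns_from_table(t1, "class"),
        class_table=t1,
        qtl_truth=truth,
        cna_groups=groups,
    )


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    alpha: float = 0.05
    bh_alpha: float = 0.05
    cna_threshold: float = 0.7
    hca_k: int = 6
    distance_variant: str = "abs"
    ward_variant: str = "classic"
    fallback_individual: bool = False
    fallback_classes: bool = True
    lenient_lines: tuple[str, ...] = ()
    control: str = "PS"
    seed: int = 0
    roi_name: str = ROI_NAME
    roi_markers: tuple[str, str] = ROI_MARKERS

    def __post_init__(self) -> None:
        for name in ("alpha", "bh_alpha", "cna_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.hca_k < 1:
            raise ValueError("hca_k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("lenient_lines", "roi_markers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def mapping_config(self, for_classes: bool = False) -> MappingConfig:
        return MappingConfig(
            fallback=self.fallback_classes if for_classes else self.fallback_individual,
            lenient_lines=frozenset(self.lenient_lines),
        )


# -------------------------------------------- study-table reconstruction

@dataclass
class ReproduceReport:
    calls_individual: list[QTLCall]
    calls_classes: list[QTLCall]
    summary_individual: dict
    summary_classes: dict
    counts: dict
    ethylene_agreement: pd.DataFrame

    @property
    def all_rows_agree(self) -> bool:
        return bool(self.ethylene_agreement["agree"].all())


def reproduce_study(config: PipelineConfig | None = None,
                    bundle: FixtureBundle | None = None) -> ReproduceReport:
    """Re-run the substitution mapping over the printed study tables.

    Individual traits are mapped in strict mode; compound classes with the
    dominant-direction fallback.  Class rows flagged uninterpretable in the
    printed table (judgement calls of the source analysis) are reported as
    NOT_INTERPRETABLE; the engine's raw status is preserved in the summary
    table for transparency.
    """
    config = config or PipelineConfig()
    bundle = bundle or load_fixture_bundle()
    imap, roi = bundle.imap, bundle.roi
    cls_by_cas = dict(
        zip(bundle.trait_table["cas"], bundle.trait_table["class"])
    )
    calls_ind = [
        map_single_qtl(p, imap, roi, config.mapping_config(False),
                       trait_class=cls_by_cas.get(p.trait, ""))
        for p in bundle.trait_patterns
    ]
    interpretable = dict(
        zip(bundle.class_table["class"],
            bundle.class_table["interpretable"].astype(int))
    )
    calls_cls = []
    for p in bundle.class_patterns:
        call = map_single_qtl(p, imap, roi, config.mapping_config(True),
                              trait_class=p.trait)
        if not interpretable.get(p.trait, 1) and call.status is QTLStatus.MAPPED:
            call = QTLCall(trait=call.trait, status=QTLStatus.NOT_INTERPRETABLE,
                           scenario="iii", trait_class=call.trait_class,
                           mode_used=call.mode_used)
        calls_cls.append(call)

    sum_ind = summarize_qtl_table(calls_ind)
    sum_cls = summarize_qtl_table(calls_cls)
    counts = {
        "n_screened_traits": len(calls_ind),
        "n_mapped_individual": sum_ind.n_mapped,
        "n_up_individual": sum_ind.n_up,
        "n_down_individual": sum_ind.n_down,
        "n_roi_individual": sum_ind.n_in_roi,
        "n_roi_up_individual": sum_ind.n_in_roi_up,
        "n_roi_down_individual": sum_ind.n_in_roi_down,
        "n_mapped_classes": sum_cls.n_mapped,
        "n_roi_classes": sum_cls.n_in_roi,
        "n_outside_total": sum_ind.n_outside + sum_cls.n_outside,
        "n_colocalizing_total": sum_ind.n_in_roi + sum_cls.n_in_roi,
        "n_total_qtls": sum_ind.n_mapped + sum_cls.n_mapped,
    }
    by_trait = {c.trait: c for c in calls_ind}
    rows = []
    for _, t in bundle.qtl_truth.iterrows():
        call = by_trait[str(t["cas"])]
        label = int(classify_ethylene(call))
        rows.append(
            {
                "order": int(t["order"]),
                "cas": t["cas"],
                "printed_ethylene": int(t["ethylene"]),
                "computed_ethylene": label,
                "printed_direction": int(t["direction"]),
                "computed_direction": call.direction,
                "mapped": call.status is QTLStatus.MAPPED,
                "agree": label == int(t["ethylene"])
                and call.status is QTLStatus.MAPPED
                and call.direction == int(t["direction"]),
            }
        )
    agreement = pd.DataFrame(rows)
    return ReproduceReport(
        calls_individual=calls_ind,
        calls_classes=calls_cls,
        summary_individual=sum_ind.as_dict(),
        summary_classes=sum_cls.as_dict(),
        counts=counts,
        ethylene_agreement=agreement,
    )
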