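"""End-to-end orchestration and recomputation of the published statistics.

Two distinct jobs live here.  ``run`` drives the synthetic study through
every analysis stage (simulate, assemble, anchor, colocalize, enrich,
classify, synteny), owns all file I/O, and emits a manifest with checksums so
any run can be reproduced from its seed and parameters.  ``verify_fixtures``
recomputes the headline statistics of the motivating cotton study from the
packaged transcriptions of its printed tables — region/TC counts, the
inside/outside stress percentages, the exact binomial tail, and the
per-chromosome candidate counts — and compares them against the printed
values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import anchoring, classification, colocalization, enrichment, synteny
from .assembly import AssemblyParams, assemble
from .anchoring import AnchorParams
from .io import read_tsv, write_fasta, write_tsv
from .simulate import SimConfig, SimulatedStudy, simulate_study

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "assemble", "anchor", "coloc", "enrich",
              "classify", "synteny")

#: Printed reference values recomputed by verify_fixtures.
REFERENCE_VALUES = {
    "colocalized_tcs": 349,
    "stress_function_tcs": 85,
    "de_genes_colocalized": 34,
    "inside_stress_pct": 35.0,
    "outside_stress_pct": 14.5,
    "overall_stress_pct": 18.2,
    "binomial_tail_bound": 7.99e-15,
    "chr10_candidates": 15,
    "chr12_candidates": 7,
    "chr11_candidates": 5,
}


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture TSV."""
    return Path(resources.files("estqtl") / "fixtures" / name)


# ---------------------------------------------------------------------------
# Fixture loaders


def load_region_fixture(fixtures_dir=None) -> pd.DataFrame:
    path = (Path(fixtures_dir) / "table2_regions.tsv") if fixtures_dir \
        else fixture_path("table2_regions.tsv")
    if not path.exists():
        raise FileNotFoundError(f"missing fixture {path}")
    return read_tsv(path)


def load_contingency_fixture(fixtures_dir=None) -> enrichment.ContingencyTable:
    path = (Path(fixtures_dir) / "table3_contingency.tsv") if fixtures_dir \
        else fixture_path("table3_contingency.tsv")
    if not path.exists():
        raise FileNotFoundError(f"missing fixture {path}")
    df = read_tsv(path).set_index("zone")
    return enrichment.ContingencyTable(
        inside_total=int(df.at["inside", "total"]),
        inside_annotated=int(df.at["inside", "annotated"]),
        inside_stress=int(df.at["inside", "stress"]),
        outside_total=int(df.at["outside", "total"]),
        outside_annotated=int(df.at["outside", "annotated"]),
        outside_stress=int(df.at["outside", "stress"]),
    )


def load_candidate_fixture_df(fixtures_dir=None) -> pd.DataFrame:
    path = (Path(fixtures_dir) / "table4_candidates.tsv") if fixtures_dir \
        else fixture_path("table4_candidates.tsv")
    if not path.exists():
        raise FileNotFoundError(f"missing fixture {path}")
    return classification.load_candidate_fixture(path)


def load_synteny_fixture(fixtures_dir=None) -> pd.DataFrame:
    path = (Path(fixtures_dir) / "table5_synteny.tsv") if fixtures_dir \
        else fixture_path("table5_synteny.tsv")
    if not path.exists():
        raise FileNotFoundError(f"missing fixture {path}")
    return read_tsv(path)


def region_fixture_as_qtls(regions: pd.DataFrame) -> pd.DataFrame:
    """Reinterpret the printed region rows as QTL intervals for re-merging."""
    return pd.DataFrame({
        "trait": regions["traits"],
        "chromosome": regions["chromosome"].astype(int),
        "ci_lo_cM": regions["ci_lo_cM"].astype(float),
        "ci_hi_cM": regions["ci_hi_cM"].astype(float),
    })


# ---------------------------------------------------------------------------
# Recomputation of the printed statistics


def recompute_reference_values(fixtures_dir=None) -> dict[str, float]:
    """Recompute every printed headline statistic from the packaged tables."""
    regions_fixture = load_region_fixture(fixtures_dir)
    merged = colocalization.merge_regions(region_fixture_as_qtls(regions_fixture))
    n_tc = int(regions_fixture["n_tc"].astype(int).sum())
    n_stress = int(regions_fixture["n_stress_function"].astype(int).sum())
    n_de = sum(int(v) for v in regions_fixture["n_de"] if str(v).strip() != "")

    table = load_contingency_fixture(fixtures_dir)
    result = enrichment.enrichment_test(table, p_rounding="report_3dp")

    candidates = load_candidate_fixture_df(fixtures_dir)
    counts = classification.regional_candidate_counts(candidates, merged)

    return {
        "n_regions": int(len(merged)),
        "colocalized_tcs": n_tc,
        "stress_function_tcs": n_stress,
        "de_genes_colocalized": n_de,
        "inside_stress_pct": result.inside_stress_pct,
        "outside_stress_pct": result.outside_stress_pct,
        "overall_stress_pct": result.overall_stress_pct,
        "binomial_tail": result.tail_probability,
        "binomial_p_background": result.p_background,
        "binomial_x": result.x,
        "binomial_n": result.n,
        "chr10_candidates": counts.get(10, 0),
        "chr12_candidates": counts.get(12, 0),
        "chr11_candidates": counts.get(11, 0),
    }


def verify_fixtures(fixtures_dir=None) -> pd.DataFrame:
    """Pass/fail table comparing recomputed statistics with printed values.

    The binomial tail is checked as a bound (the printed value rounds up the
    exact tail); every other quantity must match exactly at its printed
    precision.
    """
    values = recompute_reference_values(fixtures_dir)
    rows = []
    for name, expected in REFERENCE_VALUES.items():
        if name == "binomial_tail_bound":
            got = values["binomial_tail"]
            ok = 0.0 < got <= expected
            rows.append((name, got, expected, "<=", ok))
        else:
            got = values[name]
            rows.append((name, got, expected, "==", got == expected))
    report = pd.DataFrame(rows, columns=["target", "value", "expected",
                                         "cmp", "passed"])
    return report


# ---------------------------------------------------------------------------
# Synthetic-study pipeline


@dataclass
class RunConfig:
    """Stage selection, parameters and output location for one pipeline run."""

    outdir: Path
    sim: SimConfig = field(default_factory=SimConfig)
    assembly_params: AssemblyParams = field(default_factory=AssemblyParams)
    anchor_params: AnchorParams = field(default_factory=AnchorParams)
    p_rounding: str = "raw"
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_kwargs = raw.get("sim", {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        for tup in ("qtl_interval_width_cM", "read_length_bp",
                    "template_length_bp", "segment_width_cM",
                    "genes_per_segment", "de_class_probs"):
            if tup in sim_kwargs:
                sim_kwargs[tup] = tuple(sim_kwargs[tup])
        return cls(
            outdir=Path(raw.get("outdir", "estqtl_out")),
            sim=SimConfig(**sim_kwargs),
            assembly_params=AssemblyParams(**raw.get("assembly", {})),
            anchor_params=AnchorParams(**raw.get("anchor", {})),
            p_rounding=raw.get("p_rounding", "raw"),
            stages=tuple(raw.get("stages", ALL_STAGES)),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _tc_gene_map(membership: pd.DataFrame, truth: pd.DataFrame) -> dict[str, str]:
    """Majority source gene per TC, from read provenance (ties: smaller id)."""
    read_gene = dict(zip(truth["read_id"], truth["gene_id"]))
    out: dict[str, str] = {}
    for tc_id, grp in membership.groupby("tc_id"):
        genes = [read_gene[r] for r in grp["read_id"] if r in read_gene]
        if genes:
            counts = pd.Series(genes).value_counts()
            top = counts[counts == counts.max()].index.min()
            out[tc_id] = top
    return out


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Every output path, record count and SHA-256 checksum lands in the
    manifest together with the seed and the alignment thresholds, so the run
    is reproducible from the manifest alone.  A stage failure aborts with the
    stage name attached.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.sim.seed,
        "assembly_params": {"min_identity": config.assembly_params.min_identity,
                            "min_overlap_bp": config.assembly_params.min_overlap_bp},
        "anchor_params": {"min_identity": config.anchor_params.min_identity,
                          "min_overlap_bp": config.anchor_params.min_overlap_bp},
        "stages": {},
    }
    logger.info("thresholds: assembly %.2f/%d bp, anchoring %.2f/%d bp",
                config.assembly_params.min_identity,
                config.assembly_params.min_overlap_bp,
                config.anchor_params.min_identity,
                config.anchor_params.min_overlap_bp)
    t0 = time.perf_counter()
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            files, counts = _STAGE_IMPLS[stage](config, outdir, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in files},
            "counts": counts,
        }
    manifest["wall_seconds"] = round(time.perf_counter() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config: RunConfig, outdir: Path, state: dict):
    study = simulate_study(config.sim)
    state["study"] = study
    files = []

    def emit_tsv(df, name):
        path = outdir / name
        write_tsv(df, path)
        files.append(path)

    emit_tsv(study.markers.drop(columns=["sequence"]), "map.tsv")
    write_fasta(dict(zip(study.markers["marker_id"], study.markers["sequence"])),
                outdir / "markers.fasta")
    files.append(outdir / "markers.fasta")
    emit_tsv(study.qtls, "qtls.tsv")
    emit_tsv(study.genes.drop(columns=["template_sequence"]), "genes.tsv")
    write_fasta(dict(zip(study.genes["gene_id"], study.genes["template_sequence"])),
                outdir / "gene_templates.fasta")
    files.append(outdir / "gene_templates.fasta")
    for lib_id, reads in study.libraries.items():
        path = outdir / f"reads_{lib_id}.fasta"
        write_fasta(reads, path)
        files.append(path)
    emit_tsv(study.read_truth, "read_truth.tsv")
    emit_tsv(study.expression, "expression.tsv")
    emit_tsv(study.segments, "synteny_segments.tsv")
    emit_tsv(study.ref_genes, "synteny_ref_genes.tsv")
    counts = {"markers": len(study.markers), "qtls": len(study.qtls),
              "genes": len(study.genes),
              "reads": int(sum(len(r) for r in study.libraries.values()))}
    return files, counts


def _stage_assemble(config: RunConfig, outdir: Path, state: dict):
    study: SimulatedStudy = state["study"]
    reads = {rid: seq for lib in study.libraries.values()
             for rid, seq in lib.items()}
    result = assemble(reads, config.assembly_params)
    state["assembly"] = result
    tc_seqs = {tc.tc_id: tc.consensus for tc in result.tcs}
    state["tc_seqs"] = tc_seqs
    write_fasta(tc_seqs, outdir / "tcs.fasta")
    membership = pd.DataFrame(result.membership(), columns=["tc_id", "read_id"])
    state["membership"] = membership
    write_tsv(membership, outdir / "tc_membership.tsv")
    stats = pd.DataFrame([{"n_tc": result.stats.n_tc,
                           "n_singletons": result.stats.n_singletons,
                           "n_assemblies": result.stats.n_assemblies}])
    write_tsv(stats, outdir / "assembly_stats.tsv")
    files = [outdir / "tcs.fasta", outdir / "tc_membership.tsv",
             outdir / "assembly_stats.tsv"]
    return files, {"n_tc": result.stats.n_tc,
                   "n_singletons": result.stats.n_singletons,
                   "n_assemblies": result.stats.n_assemblies}


def _stage_anchor(config: RunConfig, outdir: Path, state: dict):
    study: SimulatedStudy = state["study"]
    hits = anchoring.map_transcripts(state["tc_seqs"], study.markers,
                                     config.anchor_params)
    state["hits"] = hits
    write_tsv(hits, outdir / "anchor_hits.tsv")
    stats = anchoring.mapping_summary(hits)
    write_tsv(pd.DataFrame([stats.__dict__]), outdir / "mapping_stats.tsv")
    return ([outdir / "anchor_hits.tsv", outdir / "mapping_stats.tsv"],
            stats.__dict__)


def _tc_tables(state: dict):
    """TC-level annotation and expression tables via majority source gene."""
    study: SimulatedStudy = state["study"]
    tc_gene = _tc_gene_map(state["membership"], study.read_truth)
    state["tc_gene"] = tc_gene
    gene_rows = study.genes.set_index("gene_id")
    ann_rows, expr_rows = [], []
    expr_by_gene: dict[str, list] = {}
    for row in study.expression.itertuples(index=False):
        expr_by_gene.setdefault(row.transcript_id, []).append(row)
    for tc_id, gene_id in tc_gene.items():
        ann_rows.append((tc_id, gene_rows.at[gene_id, "function_label"],
                         bool(gene_rows.at[gene_id, "stress_related"])))
        for row in expr_by_gene.get(gene_id, ()):
            expr_rows.append((tc_id, row.tissue, row.direction))
    annotations = pd.DataFrame(ann_rows, columns=["tc_id", "function_label",
                                                  "stress_related"])
    expression = pd.DataFrame(expr_rows, columns=["transcript_id", "tissue",
                                                  "direction"])
    return annotations, expression


def _stage_coloc(config: RunConfig, outdir: Path, state: dict):
    study: SimulatedStudy = state["study"]
    regions = colocalization.merge_regions(study.qtls)
    state["regions"] = regions
    assignments, per_region = colocalization.colocalize(
        state["hits"], regions,
        valid_chromosomes=set(range(1, config.sim.n_chromosomes + 1)))
    state["assignments"] = assignments
    state["per_region"] = per_region
    annotations, expression = _tc_tables(state)
    state["tc_annotations"] = annotations
    state["tc_expression"] = expression
    summary = colocalization.region_table(regions, per_region, annotations,
                                          expression)
    write_tsv(regions, outdir / "regions.tsv")
    write_tsv(assignments, outdir / "region_assignments.tsv")
    write_tsv(summary, outdir / "region_summary.tsv")
    files = [outdir / "regions.tsv", outdir / "region_assignments.tsv",
             outdir / "region_summary.tsv"]
    return files, {"n_regions": len(regions),
                   "colocalized_tcs": len(colocalization.colocalized_set(assignments))}


def _stage_enrich(config: RunConfig, outdir: Path, state: dict):
    mapped = list(dict.fromkeys(state["hits"]["tc_id"]))
    coloc = colocalization.colocalized_set(state["assignments"])
    table = enrichment.contingency(mapped, coloc, state["tc_annotations"])
    result = enrichment.enrichment_test(table, p_rounding=config.p_rounding)
    state["enrichment"] = result
    logger.info(enrichment.report_line(result))
    df = pd.DataFrame([{**table.__dict__,
                        "p_background": result.p_background,
                        "x": result.x, "n": result.n,
                        "tail_probability": f"{result.tail_probability:.3e}",
                        "inside_stress_pct": result.inside_stress_pct,
                        "outside_stress_pct": result.outside_stress_pct,
                        "overall_stress_pct": result.overall_stress_pct}])
    write_tsv(df, outdir / "enrichment_report.tsv")
    return [outdir / "enrichment_report.tsv"], {"x": result.x, "n": result.n}


def _stage_classify(config: RunConfig, outdir: Path, state: dict):
    study: SimulatedStudy = state["study"]
    membership = state["membership"]
    truth = study.read_truth.set_index("read_id")
    stressed_libs = {lib.library_id for lib in config.sim.libraries
                     if lib.stressed}
    coloc = colocalization.colocalized_set(state["assignments"])
    ann = state["tc_annotations"].set_index("tc_id")
    de_ids = set(state["tc_expression"]["transcript_id"])
    profiles = []
    for tc_id, grp in membership.groupby("tc_id", sort=False):
        libs = {truth.at[r, "library_id"] for r in grp["read_id"]}
        stress_go = bool(ann.at[tc_id, "stress_related"]) \
            if tc_id in ann.index and str(ann.at[tc_id, "function_label"]) else False
        profiles.append(classification.EvidenceProfile(
            transcript_id=tc_id,
            in_stress_library_unique=bool(libs) and libs <= stressed_libs,
            differentially_expressed=tc_id in de_ids,
            qtl_colocalized=tc_id in coloc,
            stress_go=stress_go,
        ))
    records = classification.classify(profiles)
    state["candidates"] = records
    table = classification.candidate_table(
        records, state["hits"], state["regions"], state["tc_annotations"],
        state["tc_expression"])
    write_tsv(table, outdir / "candidates.tsv")
    levels = pd.Series([r.level for r in records]).value_counts().to_dict()
    return [outdir / "candidates.tsv"], {"levels": levels}


def _stage_synteny(config: RunConfig, outdir: Path, state: dict):
    study: SimulatedStudy = state["study"]
    report = synteny.region_synteny_report(state["regions"], study.segments,
                                           study.ref_genes)
    write_tsv(report, outdir / "synteny_report.tsv")
    return [outdir / "synteny_report.tsv"], synteny.synteny_summary(report)


_STAGE_IMPLS = {
    "simulate": _stage_simulate,
    "assemble": _stage_assemble,
    "anchor": _stage_anchor,
    "coloc": _stage_coloc,
    "enrich": _stage_enrich,
    "classify": _stage_classify,
    "synteny": _stage_synteny,
}


__all__ = ["RunConfig", "run", "verify_fixtures", "recompute_reference_values",
           "fixture_path", "load_region_fixture", "load_contingency_fixture",
           "load_candidate_fixture_df", "load_synteny_fixture",
           "region_fixture_as_qtls", "REFERENCE_VALUES", "ALL_STAGES"]
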