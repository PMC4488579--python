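"""Synthetic EST / genetic-map / QTL generator with known ground truth.

The generator emulates the structure of a multi-library cotton EST study on a
13-chromosome consensus genetic map: sequence-tagged-site markers with random
sequences and uniform cM positions, trait-coded QTLs with 2-LOD-style
confidence intervals, gene models placed at marker positions, multi-library
single-pass reads sampled from the gene templates with substitution errors
and random strand, differential-expression labels, and syntenic reference
segments.  The one generative effect the downstream analysis is meant to
detect is explicit: a stress-annotated gene's odds of being placed inside a
merged QTL region are multiplied by ``enrichment_odds`` (theta) relative to a
non-stress gene; theta = 1 is the null.

Every stage draws from its own child random stream derived from the master
seed by a fixed spawn key (stage index), so regenerating one stage never
perturbs another.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .colocalization import merge_regions

TRAITS = ("OP", "d13C", "Chl-a", "Chl-b", "CT", "DM", "HI", "SC", "BW",
          "FF", "FS", "FL")

# Fixed spawn keys: regenerating one stage leaves the others untouched.
_STAGES = {"map": 0, "qtls": 1, "genes": 2, "ests": 3, "expression": 4,
           "synteny": 5}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STRESS_FUNCTIONS = (
    "dehydrin family protein", "late embryogenesis abundant protein",
    "heat shock protein 70", "metallothionein-like protein",
    "putative thioredoxin", "WRKY transcription factor",
    "abscisic acid responsive element binding factor",
    "osmotin-like protein", "proline-rich protein", "aquaporin PIP2",
)
OTHER_FUNCTIONS = (
    "ribosomal protein L10", "photosystem II oxygen-evolving complex",
    "ATP synthase subunit", "tubulin beta chain", "histone H3",
    "cellulose synthase", "ubiquitin extension protein",
    "glyceraldehyde-3-phosphate dehydrogenase", "actin depolymerizing factor",
    "pectin methylesterase",
)


class ConfigError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    tissue: str
    treatment: str  # control / drought / chilling / none
    n_reads: int | None = None  # overrides SimConfig.reads_per_library

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "drought", "chilling", "none"):
            raise ConfigError(f"unknown treatment {self.treatment!r}")
        if self.n_reads is not None and self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")

    @property
    def stressed(self) -> bool:
        return self.treatment in ("drought", "chilling")


def default_libraries() -> list[LibrarySpec]:
    """Ten libraries mirroring the tissue/treatment design of the EST study."""
    return [
        LibrarySpec("GH_ECOT", "etiolated cotyledon", "none"),
        LibrarySpec("GH_SDL", "seedling", "control"),
        LibrarySpec("GH_SDLD", "seedling", "drought"),
        LibrarySpec("GH_SDCH", "seedling", "chilling"),
        LibrarySpec("GH_FOX", "ovary", "none"),
        LibrarySpec("GH_MDI", "boll_8_10dpa", "control"),
        LibrarySpec("GH_MDDS", "boll_8_10dpa", "drought"),
        LibrarySpec("GH_LDI", "boll_15_20dpa", "control"),
        LibrarySpec("GH_LDDS", "boll_15_20dpa", "drought"),
        LibrarySpec("GH_STEM", "stem", "none"),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale study conditions for the synthetic cotton EST experiment.

    Distances are centimorgans, sequence lengths base pairs.  theta
    (``enrichment_odds``) multiplies a stress gene's odds of placement inside
    a merged QTL region; 1 is the no-enrichment null.  Stress-treated
    libraries oversample stress genes by ``stress_oversample``.
    """

    n_chromosomes: int = 13
    chrom_length_cM: float = 160.0
    n_markers: int = 300
    marker_length_bp: int = 400
    n_genes: int = 200
    stress_fraction: float = 0.25
    annotated_fraction: float = 0.70
    enrichment_odds: float = 3.0
    n_qtls: int = 12
    qtl_interval_width_cM: tuple[float, float] = (6.0, 20.0)
    libraries: tuple[LibrarySpec, ...] = field(
        default_factory=lambda: tuple(default_libraries()))
    reads_per_library: int = 60
    read_length_bp: tuple[int, int] = (150, 500)
    template_length_bp: tuple[int, int] = (600, 2000)
    per_base_error: float = 0.01
    stress_oversample: float = 3.0
    de_fraction: float = 0.15
    de_stress_multiplier: float = 3.0
    de_class_probs: tuple[float, float, float] = (879 / 2106, 1163 / 2106, 64 / 2106)
    n_segments: int = 20
    segment_width_cM: tuple[float, float] = (5.0, 30.0)
    genes_per_segment: tuple[int, int] = (1, 4)
    ref_stress_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stress_fraction", "annotated_fraction", "per_base_error",
                     "de_fraction", "ref_stress_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment_odds <= 0:
            raise ConfigError("enrichment_odds (theta) must be > 0")
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")
        if self.chrom_length_cM <= 0:
            raise ConfigError("chrom_length_cM must be positive")
        lo, hi = self.qtl_interval_width_cM
        if not (0 < lo <= hi):
            raise ConfigError("qtl_interval_width_cM must be a positive range")
        if hi > self.chrom_length_cM:
            raise ConfigError("QTL interval width range exceeds chromosome length")
        if abs(sum(self.de_class_probs) - 1.0) > 1e-9:
            raise ConfigError("de_class_probs must sum to 1")
        if self.template_length_bp[0] < 3 * 100:
            raise ConfigError("templates must be at least 3x the anchoring overlap")
        ids = [lib.library_id for lib in self.libraries]
        if len(ids) != len(set(ids)):
            raise ConfigError("library ids must be unique")

    def rng(self, stage: str) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGES[stage],))
        return np.random.default_rng(ss)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_map(config: SimConfig) -> pd.DataFrame:
    """Marker scaffold: unique ids, uniform cM positions, random sequences.

    Columns ``marker_id, chromosome, position_cM, sequence``; sorted by
    chromosome then position, ids assigned in that order.
    """
    rng = config.rng("map")
    n = config.n_markers
    if n == 0:
        return pd.DataFrame(columns=["marker_id", "chromosome", "position_cM",
                                     "sequence"])
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n)
    pos = rng.uniform(0.0, config.chrom_length_cM, size=n)
    order = np.lexsort((pos, chroms))
    seqs = [_random_seq(rng, config.marker_length_bp) for _ in range(n)]
    return pd.DataFrame({
        "marker_id": [f"STS_{i + 1:04d}" for i in range(n)],
        "chromosome": chroms[order],
        "position_cM": np.round(pos[order], 1),
        "sequence": [seqs[j] for j in order],
    })


def make_qtls(markers: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Trait-coded QTL confidence intervals inside chromosome bounds."""
    rng = config.rng("qtls")
    rows = []
    lo_w, hi_w = config.qtl_interval_width_cM
    for _ in range(config.n_qtls):
        trait = TRAITS[rng.integers(0, len(TRAITS))]
        chrom = int(rng.integers(1, config.n_chromosomes + 1))
        width = rng.uniform(lo_w, hi_w)
        start = rng.uniform(0.0, config.chrom_length_cM - width)
        rows.append((trait, chrom, round(start, 1), round(start + width, 1)))
    return pd.DataFrame(rows, columns=["trait", "chromosome", "ci_lo_cM",
                                       "ci_hi_cM"])


def _marker_zones(markers: pd.DataFrame, regions: pd.DataFrame
                  ) -> tuple[list[int], list[int]]:
    inside, outside = [], []
    for idx, row in enumerate(markers.itertuples(index=False)):
        hit = not regions.empty and bool((
            (regions["chromosome"] == row.chromosome)
            & (regions["lo_cM"] <= row.position_cM)
            & (row.position_cM <= regions["hi_cM"])).any())
        (inside if hit else outside).append(idx)
    return inside, outside


def make_genes(markers: pd.DataFrame, qtls: pd.DataFrame, config: SimConfig,
               with_templates: bool = True) -> pd.DataFrame:
    """Gene models at marker positions with a theta-controlled zone bias.

    Each gene sits on a marker (its template embeds the marker sequence, so
    anchoring can recover the locus).  Baseline inside-region placement
    probability is the inside fraction of markers; for stress-annotated genes
    the inside odds are multiplied by theta.  Within a zone, distinct markers
    are preferred until exhausted.  Columns: ``gene_id, chromosome,
    position_cM, marker_id, template_sequence, function_label,
    stress_related, in_qtl_truth``.

    Placement, annotation and stress variates are drawn before any template
    nucleotide, so ``with_templates=False`` (for placement-only studies)
    yields exactly the same truth columns with an empty template column.
    """
    if config.enrichment_odds <= 0:  # belt and braces; SimConfig validates too
        raise ConfigError("enrichment_odds (theta) must be > 0")
    if markers.empty:
        raise ConfigError("gene placement requires a non-empty marker map")
    rng = config.rng("genes")
    regions = merge_regions(qtls)
    inside, outside = _marker_zones(markers, regions)
    p0 = len(inside) / len(markers)
    theta = config.enrichment_odds
    if 0.0 < p0 < 1.0:
        odds = p0 / (1.0 - p0)
        p_stress = (theta * odds) / (1.0 + theta * odds)
    else:
        p_stress = p0
    lo_t, hi_t = config.template_length_bp
    mlen = config.marker_length_bp

    stress_flags = rng.random(config.n_genes) < config.stress_fraction
    zone_draws = rng.random(config.n_genes)
    annotated = rng.random(config.n_genes) < config.annotated_fraction
    label_draws = rng.integers(0, len(STRESS_FUNCTIONS), size=config.n_genes)
    # Distinct-marker preference: shuffled per-zone queues, refilled on
    # exhaustion, keep one gene per marker while markers last.
    queues = {True: list(rng.permutation(inside)) if inside else [],
              False: list(rng.permutation(outside)) if outside else []}
    chosen: list[int] = []
    zones: list[bool] = []
    for g in range(config.n_genes):
        stress = bool(stress_flags[g])
        p_in = p_stress if stress else p0
        want_inside = bool(zone_draws[g] < p_in)
        if want_inside and not inside:
            want_inside = False
        if not want_inside and not outside:
            want_inside = True
        if not queues[want_inside]:
            pool = inside if want_inside else outside
            queues[want_inside] = list(rng.permutation(pool))
        chosen.append(int(queues[want_inside].pop()))
        zones.append(want_inside)
    m_ids = markers["marker_id"].tolist()
    m_chrom = markers["chromosome"].to_numpy()
    m_pos = markers["position_cM"].to_numpy()
    m_seq = markers["sequence"].tolist()
    rows = []
    for g in range(config.n_genes):
        midx = chosen[g]
        stress = bool(stress_flags[g])
        if with_templates:
            tlen = int(rng.integers(lo_t, hi_t + 1))
            insert_at = int(rng.integers(0, tlen - mlen + 1))
            template = (_random_seq(rng, insert_at) + m_seq[midx]
                        + _random_seq(rng, tlen - mlen - insert_at))
        else:
            template = ""
        if annotated[g]:
            vocab = STRESS_FUNCTIONS if stress else OTHER_FUNCTIONS
            label = vocab[int(label_draws[g]) % len(vocab)]
        else:
            label = ""
        rows.append((f"G{g + 1:04d}", int(m_chrom[midx]), float(m_pos[midx]),
                     m_ids[midx], template, label, stress, zones[g]))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "position_cM",
                                       "marker_id", "template_sequence",
                                       "function_label", "stress_related",
                                       "in_qtl_truth"])


_BYTE_TO_CODE = np.zeros(256, dtype=np.int8)
for _ci, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _ci


def _revcomp_str(seq: str) -> str:
    from ._seqops import revcomp

    return revcomp(seq)


def make_ests(genes: pd.DataFrame, config: SimConfig
              ) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Per-library reads from gene templates, plus a provenance truth table.

    Reads are random subsequences with substitution errors at
    ``per_base_error`` and reverse-complemented with probability 0.5.
    Stress-treated libraries weight stress genes by ``stress_oversample``.
    Returns ``({library_id: {read_id: seq}}, truth)`` with truth columns
    ``read_id, library_id, gene_id, strand, start, length, n_errors``.
    """
    if not config.libraries:
        raise ConfigError("at least one library is required")
    lo_r, hi_r = config.read_length_bp
    min_template = int(genes["template_sequence"].str.len().min()) if not genes.empty else 0
    if genes.empty:
        raise ConfigError("no genes to sample reads from")
    if lo_r > min_template:
        raise ConfigError(
            f"minimum read length {lo_r} exceeds shortest template {min_template}")
    rng = config.rng("ests")
    templates = genes["template_sequence"].tolist()
    gene_ids = genes["gene_id"].tolist()
    stress = genes["stress_related"].to_numpy(dtype=bool)
    libraries: dict[str, dict[str, str]] = {}
    truth_rows = []
    for lib in config.libraries:
        weights = np.where(stress, config.stress_oversample, 1.0) if lib.stressed \
            else np.ones(len(genes))
        weights = weights / weights.sum()
        reads: dict[str, str] = {}
        n_reads = lib.n_reads if lib.n_reads is not None else config.reads_per_library
        for i in range(n_reads):
            g = int(rng.choice(len(genes), p=weights))
            template = templates[g]
            max_len = min(hi_r, len(template))
            length = int(rng.integers(lo_r, max_len + 1))
            start = int(rng.integers(0, len(template) - length + 1))
            fragment = np.frombuffer(
                template[start : start + length].encode(), dtype=np.uint8)
            codes = _BYTE_TO_CODE[fragment].astype(np.int64)
            err_mask = rng.random(length) < config.per_base_error
            n_err = int(err_mask.sum())
            if n_err:
                shifts = rng.integers(1, 4, size=n_err)
                codes[err_mask] = (codes[err_mask] + shifts) % 4
            seq = _BASES[codes].tobytes().decode("ascii")
            strand = "-" if rng.random() < 0.5 else "+"
            if strand == "-":
                seq = _revcomp_str(seq)
            read_id = f"{lib.library_id}_r{i + 1:05d}"
            reads[read_id] = seq
            truth_rows.append((read_id, lib.library_id, gene_ids[g], strand,
                               start, length, n_err))
        libraries[lib.library_id] = reads
    truth = pd.DataFrame(truth_rows, columns=["read_id", "library_id",
                                              "gene_id", "strand", "start",
                                              "length", "n_errors"])
    return libraries, truth


def make_expression(genes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Differential-expression labels: ``transcript_id, tissue, direction``.

    A gene is labelled with probability ``de_fraction`` (times
    ``de_stress_multiplier`` for stress genes, capped at 1); the direction is
    drawn from ``de_class_probs`` over (induced, repressed, reciprocal) and
    the tissue uniformly from leaf/root.
    """
    rng = config.rng("expression")
    directions = ("induced", "repressed", "reciprocal")
    rows = []
    p_plain = config.de_fraction
    p_stress = min(1.0, config.de_fraction * config.de_stress_multiplier)
    for row in genes.itertuples(index=False):
        p = p_stress if row.stress_related else p_plain
        if rng.random() >= p:
            continue
        direction = directions[int(rng.choice(3, p=config.de_class_probs))]
        tissue = "leaf" if rng.random() < 0.5 else "root"
        rows.append((row.gene_id, tissue, direction))
    return pd.DataFrame(rows, columns=["transcript_id", "tissue", "direction"])


def make_synteny(markers: pd.DataFrame, config: SimConfig
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Syntenic segments on the cotton map plus reference gene annotations.

    Segments are cM intervals inside chromosome bounds tagged with reference
    block ids; each carries 1+ reference genes with a function label and a
    stress flag.
    """
    rng = config.rng("synteny")
    seg_rows, gene_rows = [], []
    lo_w, hi_w = config.segment_width_cM
    glo, ghi = config.genes_per_segment
    serial = 0
    for i in range(config.n_segments):
        chrom = int(rng.integers(1, config.n_chromosomes + 1))
        width = rng.uniform(lo_w, min(hi_w, config.chrom_length_cM))
        start = rng.uniform(0.0, config.chrom_length_cM - width)
        seg_id = f"D{int(rng.integers(1, 24)):02d}.{i + 1}"
        seg_rows.append((seg_id, chrom, round(start, 1), round(start + width, 1)))
        for _ in range(int(rng.integers(glo, ghi + 1))):
            serial += 1
            stress = bool(rng.random() < config.ref_stress_fraction)
            vocab = STRESS_FUNCTIONS if stress else OTHER_FUNCTIONS
            func = vocab[int(rng.integers(0, len(vocab)))]
            gene_rows.append((f"AT{int(rng.integers(1, 6))}G{serial:05d}",
                              seg_id, func, stress))
    segments = pd.DataFrame(seg_rows, columns=["segment_id", "chromosome",
                                               "lo_cM", "hi_cM"])
    ref_genes = pd.DataFrame(gene_rows, columns=["gene_id", "segment_id",
                                                 "function_text",
                                                 "stress_related"])
    return segments, ref_genes


@dataclass
class SimulatedStudy:
    config: SimConfig
    markers: pd.DataFrame
    qtls: pd.DataFrame
    genes: pd.DataFrame
    libraries: dict[str, dict[str, str]]
    read_truth: pd.DataFrame
    expression: pd.DataFrame
    segments: pd.DataFrame
    ref_genes: pd.DataFrame

    @property
    def annotations(self) -> pd.DataFrame:
        """Gene-level annotation table keyed like downstream TC annotations."""
        return self.genes.rename(columns={"gene_id": "tc_id"})[
            ["tc_id", "function_label", "stress_related"]]


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run every generator stage under one master seed."""
    markers = make_map(config)
    qtls = make_qtls(markers, config)
    genes = make_genes(markers, qtls, config)
    libraries, truth = make_ests(genes, config)
    expression = make_expression(genes, config)
    segments, ref_genes = make_synteny(markers, config)
    return SimulatedStudy(config, markers, qtls, genes, libraries, truth,
                          expression, segments, ref_genes)


__all__ = ["SimConfig", "LibrarySpec", "SimulatedStudy", "ConfigError",
           "default_libraries", "make_map", "make_qtls", "make_genes",
           "make_ests", "make_expression", "make_synteny", "simulate_study",
           "TRAITS", "STRESS_FUNCTIONS", "OTHER_FUNCTIONS"]
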