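"""Synthetic-study generator: determinism, conservation, generative effects."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from estqtl.simulate import (ConfigError, LibrarySpec, SimConfig,
                             default_libraries, make_ests, make_expression,
                             make_genes, make_map, make_qtls, make_synteny,
                             simulate_study)
from estqtl._seqops import revcomp


BASE = SimConfig(seed=7)


class TestConfig:
    def test_zero_chromosomes_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_chromosomes=0)

    def test_theta_must_be_positive(self):
        with pytest.raises(ConfigError):
            SimConfig(enrichment_odds=0.0)

    def test_qtl_width_cannot_exceed_chromosome(self):
        with pytest.raises(ConfigError):
            SimConfig(chrom_length_cM=10.0, qtl_interval_width_cM=(5.0, 20.0))

    def test_duplicate_library_ids_rejected(self):
        lib = LibrarySpec("L1", "leaf", "control")
        with pytest.raises(ConfigError):
            SimConfig(libraries=(lib, lib))


class TestMakeMap:
    def test_zero_markers_yield_valid_empty_table(self):
        table = make_map(replace(BASE, n_markers=0))
        assert table.empty
        assert list(table.columns) == ["marker_id", "chromosome",
                                       "position_cM", "sequence"]

    def test_deterministic_given_seed(self):
        a = make_map(BASE)
        b = make_map(SimConfig(seed=7))
        assert a.equals(b)
        assert not a.equals(make_map(SimConfig(seed=8)))

    def test_counts_positions_and_uniqueness(self):
        cfg = replace(BASE, n_markers=500)
        table = make_map(cfg)
        assert len(table) == 500
        assert table["marker_id"].is_unique
        assert table["chromosome"].between(1, cfg.n_chromosomes).all()
        assert table["position_cM"].between(0, cfg.chrom_length_cM).all()
        # every chromosome populated at this density
        assert table["chromosome"].nunique() == cfg.n_chromosomes
        assert (table["sequence"].str.len() == cfg.marker_length_bp).all()


class TestMakeQtls:
    def test_zero_qtls(self):
        markers = make_map(BASE)
        assert make_qtls(markers, replace(BASE, n_qtls=0)).empty

    def test_all_widths_within_configured_range(self):
        cfg = replace(BASE, n_qtls=1000, qtl_interval_width_cM=(6.0, 20.0))
        qtls = make_qtls(make_map(cfg), cfg)
        widths = qtls["ci_hi_cM"] - qtls["ci_lo_cM"]
        # rounding to 0.1 cM can nudge a width just past the bounds
        assert widths.between(5.9, 20.1).all()
        assert (qtls["ci_lo_cM"] >= 0).all()
        assert (qtls["ci_hi_cM"] <= cfg.chrom_length_cM).all()

    def test_deterministic_given_seed(self):
        markers = make_map(BASE)
        assert make_qtls(markers, BASE).equals(make_qtls(markers, SimConfig(seed=7)))


class TestMakeGenes:
    def test_null_theta_equalises_zone_rates(self):
        """theta=1: stress and non-stress genes land inside at the same rate."""
        cfg = replace(BASE, n_genes=5000, enrichment_odds=1.0)
        markers = make_map(cfg)
        qtls = make_qtls(markers, cfg)
        diffs = []
        for seed in (0, 1, 2):
            genes = make_genes(markers, qtls, replace(cfg, seed=seed),
                               with_templates=False)
            s = genes[genes["stress_related"]]
            ns = genes[~genes["stress_related"]]
            diffs.append(s["in_qtl_truth"].mean() - ns["in_qtl_truth"].mean())
        # pooled over 3 x 5000 genes the rate difference is within
        # two-proportion sampling error of zero
        assert abs(np.mean(diffs)) < 0.02

    def test_huge_theta_forces_stress_genes_inside(self):
        cfg = replace(BASE, n_genes=2000, enrichment_odds=1e6)
        markers = make_map(cfg)
        qtls = make_qtls(markers, cfg)
        genes = make_genes(markers, qtls, cfg, with_templates=False)
        stress = genes[genes["stress_related"]]
        assert stress["in_qtl_truth"].mean() > 0.999

    def test_recovers_target_odds_ratio(self):
        """theta = 3.12: truth-table odds ratio within 25% over three seeds."""
        cfg = replace(BASE, n_genes=5000, enrichment_odds=3.12)
        markers = make_map(cfg)
        qtls = make_qtls(markers, cfg)
        ors = []
        for seed in (0, 1, 2):
            g = make_genes(markers, qtls, replace(cfg, seed=seed),
                           with_templates=False)
            s = g[g["stress_related"]]["in_qtl_truth"].mean()
            ns = g[~g["stress_related"]]["in_qtl_truth"].mean()
            ors.append((s / (1 - s)) / (ns / (1 - ns)))
        assert np.mean(ors) == pytest.approx(3.12, rel=0.25)

    def test_templates_embed_marker_and_respect_bounds(self):
        cfg = replace(BASE, n_genes=30)
        markers = make_map(cfg)
        genes = make_genes(markers, make_qtls(markers, cfg), cfg)
        seq_by_marker = dict(zip(markers["marker_id"], markers["sequence"]))
        lo, hi = cfg.template_length_bp
        for row in genes.itertuples(index=False):
            assert lo <= len(row.template_sequence) <= hi
            assert seq_by_marker[row.marker_id] in row.template_sequence

    def test_gene_position_matches_its_marker(self):
        cfg = replace(BASE, n_genes=50)
        markers = make_map(cfg)
        genes = make_genes(markers, make_qtls(markers, cfg), cfg,
                           with_templates=False)
        pos = markers.set_index("marker_id")["position_cM"]
        for row in genes.itertuples(index=False):
            assert row.position_cM == pos[row.marker_id]


class TestMakeEsts:
    def test_error_free_reads_are_template_substrings(self):
        cfg = replace(BASE, per_base_error=0.0, reads_per_library=20)
        study_genes = make_genes(make_map(cfg),
                                 make_qtls(make_map(cfg), cfg), cfg)
        libraries, truth = make_ests(study_genes, cfg)
        templates = dict(zip(study_genes["gene_id"],
                             study_genes["template_sequence"]))
        for row in truth.itertuples(index=False):
            seq = libraries[row.library_id][row.read_id]
            if row.strand == "-":
                seq = revcomp(seq)
            assert seq == templates[row.gene_id][row.start:row.start + row.length]

    def test_per_library_read_count_override(self):
        libs = (LibrarySpec("L1", "leaf", "control", n_reads=0),
                LibrarySpec("L2", "leaf", "drought"))
        cfg = replace(BASE, libraries=libs, reads_per_library=15)
        markers = make_map(cfg)
        genes = make_genes(markers, make_qtls(markers, cfg), cfg)
        libraries, truth = make_ests(genes, cfg)
        assert libraries["L1"] == {}
        assert len(libraries["L2"]) == 15
        assert set(truth["library_id"]) == {"L2"}

    def test_empirical_error_rate_matches_configuration(self):
        """0.02 per-base error: realised mismatch rate 0.02 +/- 0.002."""
        libs = (LibrarySpec("BIG", "leaf", "control", n_reads=10_000),)
        cfg = replace(BASE, libraries=libs, per_base_error=0.02, n_genes=50)
        markers = make_map(cfg)
        genes = make_genes(markers, make_qtls(markers, cfg), cfg)
        libraries, truth = make_ests(genes, cfg)
        templates = dict(zip(genes["gene_id"], genes["template_sequence"]))
        mism = total = 0
        for row in truth.itertuples(index=False):
            seq = libraries["BIG"][row.read_id]
            if row.strand == "-":
                seq = revcomp(seq)
            ref = templates[row.gene_id][row.start:row.start + row.length]
            mism += sum(a != b for a, b in zip(seq, ref))
            total += row.length
        assert mism / total == pytest.approx(0.02, abs=0.002)

    def test_stressed_libraries_oversample_stress_genes(self):
        libs = (LibrarySpec("CTRL", "leaf", "control", n_reads=3000),
                LibrarySpec("DRT", "leaf", "drought", n_reads=3000))
        cfg = replace(BASE, libraries=libs, n_genes=200)
        markers = make_map(cfg)
        genes = make_genes(markers, make_qtls(markers, cfg), cfg)
        _, truth = make_ests(genes, cfg)
        stress_ids = set(genes.loc[genes["stress_related"], "gene_id"])
        rate = {lib: truth.loc[truth["library_id"] == lib, "gene_id"]
                .isin(stress_ids).mean() for lib in ("CTRL", "DRT")}
        assert rate["DRT"] > 1.5 * rate["CTRL"]

    def test_read_length_beyond_template_rejected(self):
        cfg = replace(BASE, read_length_bp=(5000, 6000))
        markers = make_map(cfg)
        genes = make_genes(markers, make_qtls(markers, cfg), cfg)
        with pytest.raises(ConfigError, match="read length"):
            make_ests(genes, cfg)

    def test_every_read_in_exactly_one_library_and_truth_row(self):
        study = simulate_study(replace(BASE, reads_per_library=10,
                                       n_genes=40, n_markers=80))
        all_ids = [rid for lib in study.libraries.values() for rid in lib]
        assert len(all_ids) == len(set(all_ids))
        assert sorted(all_ids) == sorted(study.read_truth["read_id"])


class TestMakeExpression:
    def test_zero_fraction_gives_empty_table(self):
        markers = make_map(BASE)
        genes = make_genes(markers, make_qtls(markers, BASE), BASE,
                           with_templates=False)
        table = make_expression(genes, replace(BASE, de_fraction=0.0))
        assert table.empty

    def test_full_fraction_labels_every_gene(self):
        markers = make_map(BASE)
        genes = make_genes(markers, make_qtls(markers, BASE), BASE,
                           with_templates=False)
        table = make_expression(genes, replace(BASE, de_fraction=1.0))
        assert sorted(table["transcript_id"]) == sorted(genes["gene_id"])

    def test_direction_proportions_match_configured_classes(self):
        """(879, 1163, 64)/2106 class split recovered within 3 points."""
        cfg = replace(BASE, n_genes=2106, de_fraction=1.0)
        markers = make_map(cfg)
        genes = make_genes(markers, make_qtls(markers, cfg), cfg,
                           with_templates=False)
        table = make_expression(genes, cfg)
        props = table["direction"].value_counts(normalize=True)
        assert props["induced"] == pytest.approx(879 / 2106, abs=0.03)
        assert props["repressed"] == pytest.approx(1163 / 2106, abs=0.03)
        assert props["reciprocal"] == pytest.approx(64 / 2106, abs=0.03)


class TestMakeSynteny:
    def test_zero_segments_give_empty_tables(self):
        markers = make_map(BASE)
        segments, genes = make_synteny(markers, replace(BASE, n_segments=0))
        assert segments.empty and genes.empty

    def test_segments_within_chromosome_bounds(self):
        cfg = replace(BASE, n_segments=200)
        segments, genes = make_synteny(make_map(cfg), cfg)
        assert (segments["lo_cM"] >= 0).all()
        assert (segments["hi_cM"] <= cfg.chrom_length_cM).all()
        assert (segments["lo_cM"] <= segments["hi_cM"]).all()
        assert segments["segment_id"].is_unique
        assert genes["segment_id"].isin(set(segments["segment_id"])).all()

    def test_deterministic_given_seed(self):
        markers = make_map(BASE)
        s1, g1 = make_synteny(markers, BASE)
        s2, g2 = make_synteny(markers, SimConfig(seed=7))
        assert s1.equals(s2) and g1.equals(g2)


class TestStudyDeterminism:
    def test_identical_config_and_seed_reproduce_everything(self):
        cfg = replace(BASE, reads_per_library=8, n_genes=30, n_markers=60)
        a = simulate_study(cfg)
        b = simulate_study(replace(cfg))
        assert a.markers.equals(b.markers)
        assert a.qtls.equals(b.qtls)
        assert a.genes.equals(b.genes)
        assert a.libraries == b.libraries
        assert a.read_truth.equals(b.read_truth)
        assert a.expression.equals(b.expression)
        assert a.segments.equals(b.segments)
        assert a.ref_genes.equals(b.ref_genes)

    def test_stage_streams_are_independent(self):
        """Changing a late-stage knob leaves earlier stages byte-identical."""
        cfg = replace(BASE, n_genes=30, n_markers=60, reads_per_library=5)
        tweaked = replace(cfg, n_segments=cfg.n_segments + 5)
        assert make_map(cfg).equals(make_map(tweaked))
        m = make_map(cfg)
        assert make_qtls(m, cfg).equals(make_qtls(m, tweaked))
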