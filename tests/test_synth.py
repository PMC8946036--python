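import filecmp

import numpy as np
import pytest

from circlact import annotate, synth
from circlact._seq import count_occurrences, revcomp
from circlact.detect import CircCall
from circlact.synth import CATEGORIES, SyntheticConfig


def small_config(**kw):
    defaults = dict(
        seed=3,
        n_circ_per_category={c: 2 for c in CATEGORIES},
        n_background_reads=20,
        n_mrnas=4,
        n_mirnas=8,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SyntheticConfig(nb_dispersion=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(de_fraction=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(circ_length_range=(100, 50))
        with pytest.raises(ValueError):
            SyntheticConfig(n_circ_per_category={"nonsense": 1})


class TestGenome:
    def test_chromosome_and_gene_counts(self):
        cfg = small_config(n_chromosomes=2, n_genes=6)
        genome, models = synth.generate_genome(cfg)
        assert len(genome) == 2
        assert len(models) == 6
        lo, hi = cfg.exons_per_gene
        assert all(lo <= len(gm.exons) <= hi for gm in models)
        assert {gm.strand for gm in models} == {"+", "-"}

    def test_too_short_chromosome_raises(self):
        cfg = small_config(chrom_length=6_000, n_genes=20,
                           circ_length_range=(48, 500))
        with pytest.raises(synth.GenerationError, match="too short"):
            synth.generate_genome(cfg)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_config()
        synth.generate_study(cfg, tmp_path / "a")
        synth.generate_study(cfg, tmp_path / "b")
        names = [p.name for p in sorted((tmp_path / "a").iterdir())]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == []
        assert len(match) == len(names) > 0


class TestPlantedCircles:
    def test_counts_and_flanks(self):
        cfg = small_config()
        genome, models = synth.generate_genome(cfg)
        circles = synth.plant_circles(cfg, genome, models)
        assert len(circles) == 2 * len(CATEGORIES)
        for circ in circles:
            iv = circ.interval
            seq = genome[iv.chrom].decode()
            left = seq[iv.start - 2 : iv.start]
            right = seq[iv.end : iv.end + 2]
            if iv.strand == "+":
                assert (left, right) == ("AG", "GT")
            else:  # reverse complement pair on the forward reference
                assert (left, right) == ("AC", "CT")

    def test_categories_rederived_by_classifier(self, study):
        """Planted labels agree 100% with span classification."""
        calls = [
            CircCall(c.circ_id, c.interval, 1, c.splice_signal, [])
            for c in study.truth.circles
        ]
        anns = annotate.annotate_calls(calls, study.models, study.genome)
        for circ, ann in zip(study.truth.circles, anns):
            assert ann.category == circ.category, circ.circ_id

    def test_impossible_category_raises(self):
        cfg = small_config(n_genes=2, n_chromosomes=1,
                           n_circ_per_category={"IciRNA": 500})
        genome, models = synth.generate_genome(cfg)
        with pytest.raises(synth.GenerationError, match="IciRNA"):
            synth.plant_circles(cfg, genome, models)


class TestReads:
    def test_junction_read_count_identity(self):
        cfg = small_config(junction_reads_per_circ=(2, 2), n_background_reads=0)
        genome, models = synth.generate_genome(cfg)
        circles = synth.plant_circles(cfg, genome, models)
        reads = synth.simulate_reads(cfg, circles, genome)
        assert len(reads) == 2 * len(circles)

    def test_junction_read_halves_map_to_circle_ends(self):
        cfg = small_config(junction_reads_per_circ=(1, 1), n_background_reads=0)
        genome, models = synth.generate_genome(cfg)
        circles = synth.plant_circles(cfg, genome, models)
        reads = synth.simulate_reads(cfg, circles, genome)
        by_id = {c.circ_id: c for c in circles}
        for read in reads:
            circ = by_id[read.read_id.split("|")[0]]
            iv = circ.interval
            seq = read.sequence if iv.strand == "+" else revcomp(read.sequence)
            chrom = genome[iv.chrom].decode()
            # some prefix comes from the circle end, the rest from its start
            found = any(
                seq[:b] == chrom[iv.end - b : iv.end]
                and seq[b:] == chrom[iv.start : iv.start + len(seq) - b]
                for b in range(1, len(seq))
            )
            assert found, read.read_id


class TestCounts:
    def test_null_fraction_means_no_de(self):
        cfg = small_config(de_fraction=0.0)
        genome, models = synth.generate_genome(cfg)
        circles = synth.plant_circles(cfg, genome, models)
        _, de, _, _ = synth.simulate_counts(cfg, circles)
        assert (de["true_log2fc"] == 0).all()
        assert (de["label"] == "null").all()

    def test_nb_moments_match_formula(self):
        """Sample variance over 10,000 draws matches mu + alpha mu^2."""
        rng = np.random.default_rng(42)
        draws = synth.nb_draw(rng, np.full(10_000, 100.0), 0.1)
        expected_var = 100 + 0.1 * 100**2  # 1100
        # sampling error of the variance of an NB at these moments
        se = np.sqrt(2 * expected_var**2 / len(draws))
        assert abs(draws.mean() - 100) < 3 * np.sqrt(expected_var / len(draws))
        assert abs(draws.var(ddof=1) - expected_var) < 4 * se

    def test_zero_dispersion_is_poisson(self):
        rng = np.random.default_rng(1)
        draws = synth.nb_draw(rng, np.full(10_000, 50.0), 0.0)
        # Poisson: variance ~ mean
        assert abs(draws.var(ddof=1) / draws.mean() - 1.0) < 0.1

    def test_negative_dispersion_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            synth.nb_draw(rng, np.array([10.0]), -0.5)


class TestPlantedMres:
    def test_planted_counts_are_exact_in_sequence(self, study):
        """Each truth row's site count equals the literal number of
        seed-complement occurrences; non-planted miRNAs never occur."""
        site_of = {
            m: revcomp(synth.mirna_seed(s)) for m, s in study.mirnas.items()
        }
        seqs = dict(study.circ_seqs) | dict(study.mrna_seqs)
        truth = study.truth.mres
        planted = {
            (r.rna_id, r.mirna_id): r.count for r in truth.itertuples(index=False)
        }
        for rna_id, seq in seqs.items():
            for mirna_id, site in site_of.items():
                expected = planted.get((rna_id, mirna_id), 0)
                assert count_occurrences(seq, site) == expected

    def test_duplicate_seeds_rejected(self):
        cfg = small_config()
        genome, models = synth.generate_genome(cfg)
        circles = synth.plant_circles(cfg, genome, models)
        mirnas = {"a": "A" * 22, "b": "A" * 22}
        with pytest.raises(ValueError, match="identical seed"):
            synth.plant_mres(cfg, circles, mirnas=mirnas)

    def test_sequence_too_short_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(synth.GenerationError, match="too short"):
            synth._plant_sites_in_sequence(
                rng, 30, [("m", "AAACCCT")] * 3, {"m": "AAACCCT"}
            )
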