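import numpy as np
import pytest

from scires.genotyping import call_sample
from scires.io_formats import read_gtf, read_pileup
from scires.synthetic_data import (SimConfig, emit_dataset, generate_bundle,
                                   simulate_individual, simulate_meiosis)

TINY = dict(n_chromosomes=1, chrom_length=60_000, n_genes=6,
            snp_density=5e-4, n_oocytes=2,
            amplification_modes=("MDA_like", "DOPPCR_like"))


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSimulateIndividual:
    def test_zero_density_no_snps(self):
        cfg = SimConfig(snp_density=0.0, **{k: v for k, v in TINY.items()
                                            if k != "snp_density"})
        with pytest.warns(UserWarning):
            diploid = simulate_individual(cfg)
        assert len(diploid.snps) == 0

    def test_seed_determinism(self):
        cfg = SimConfig(**TINY)
        a = simulate_individual(cfg)
        b = simulate_individual(cfg)
        assert a.snps.equals(b.snps)
        assert all(np.array_equal(a.ref[c], b.ref[c]) for c in a.ref)

    def test_snp_count_within_sampling_bounds(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000_000,
                        snp_density=1e-3)
        diploid = simulate_individual(cfg)
        mean, sd = 1000, np.sqrt(1000 * (1 - 1e-3))
        assert abs(len(diploid.snps) - mean) < 5 * sd

    def test_alleles_distinct(self):
        diploid = simulate_individual(SimConfig(**TINY))
        assert (diploid.snps["ref_base"] != diploid.snps["alt_base"]).all()
        for row in diploid.snps.itertuples():
            assert {row.hom1_base, row.hom2_base} == \
                {row.ref_base, row.alt_base}


class TestSimulateMeiosis:
    def test_zero_crossovers_all_hom(self):
        cfg = SimConfig(crossovers_per_chromosome=0, **TINY)
        diploid = simulate_individual(cfg)
        product = simulate_meiosis(diploid, cfg, _rng(1))
        assert (product.truth["oocyte_status"] == "hom").all()
        assert (product.truth["pb1_status"] == "hom").all()

    def test_single_crossover_het_exactly_distal(self):
        cfg = SimConfig(**TINY)
        diploid = simulate_individual(cfg)
        product = simulate_meiosis(diploid, cfg, _rng(2))
        (x,) = product.crossovers["chr1"]
        truth = product.truth
        het_truth = truth["pos"] > x
        assert ((truth["oocyte_status"] == "het") == het_truth).all()
        assert ((truth["pb1_status"] == "het") == het_truth).all()

    def test_oocyte_and_pb1_het_sets_coincide(self):
        cfg = SimConfig(crossovers_per_chromosome=3, **TINY)
        diploid = simulate_individual(cfg)
        product = simulate_meiosis(diploid, cfg, _rng(3))
        truth = product.truth
        assert (truth["oocyte_status"] == truth["pb1_status"]).all()

    def test_hom_alleles_complementary_between_oocyte_and_pb1(self):
        """At non-recombined sites the oocyte's allele and the PB1's
        allele together are the two parental alleles."""
        cfg = SimConfig(**TINY)
        diploid = simulate_individual(cfg)
        product = simulate_meiosis(diploid, cfg, _rng(4))
        snp_alleles = {(r.chrom, r.pos): {r.ref_base, r.alt_base}
                       for r in diploid.snps.itertuples()}
        hom = product.truth[product.truth["oocyte_status"] == "hom"]
        for row in hom.itertuples():
            oo = set(row.oocyte_bases.split("/"))
            pb = set(row.pb1_bases.split("/"))
            assert len(oo) == 1 and len(pb) == 1
            assert oo | pb == snp_alleles[(row.chrom, row.pos)]


class TestPileupSynthesis:
    def test_error_free_hom_site_is_pure(self):
        cfg = SimConfig(seq_error_rate=0.0, snp_density=0.0,
                        **{k: v for k, v in TINY.items()
                           if k != "snp_density"})
        with pytest.warns(UserWarning):
            bundle = generate_bundle(cfg)
        for col in bundle.dna_pileups["liver"].iter_columns():
            assert set(b for b, _ in col.counts) == {col.ref_base}

    def test_het_site_allele_fraction_concentrates(self):
        """At a heterozygous site the alt fraction approaches 1/2."""
        cfg = SimConfig(dna_depth_mean=2000, seq_error_rate=0.0, **TINY)
        bundle = generate_bundle(cfg)
        snps = set(zip(bundle.diploid.snps["chrom"],
                       bundle.diploid.snps["pos"]))
        checked = 0
        for col in bundle.dna_pileups["liver"].iter_columns():
            if (col.chrom, col.pos) in snps and col.depth > 500:
                alt = max(col.base_count(b) for b in "ACGT"
                          if b != col.ref_base)
                assert abs(alt / col.depth - 0.5) < 0.1
                checked += 1
        assert checked > 5

    def test_realized_coverage_near_configured(self):
        bundle = generate_bundle(SimConfig(**TINY))
        cfg = bundle.config
        genome = cfg.n_chromosomes * cfg.chrom_length
        for i, name in enumerate(cfg.oocyte_names):
            target = cfg.covered_fraction[cfg.amplification_modes[i]]
            realized = bundle.dna_pileups[name].covered_bp / genome
            # run-level binomial bound: ~G/mean_run covered runs
            n_runs = genome * target / \
                cfg.mean_covered_run[cfg.amplification_modes[i]]
            sd = np.sqrt(target * (1 - target) / n_runs)
            assert abs(realized - target) < 5 * sd + 0.02

    def test_low_coverage_samples_have_low_overlap(self):
        """Two independent DOP-PCR-like samples at fraction f overlap on
        about f of either covered set."""
        cfg = SimConfig(n_chromosomes=1, chrom_length=200_000, n_genes=20,
                        n_oocytes=2,
                        amplification_modes=("DOPPCR_like", "DOPPCR_like"))
        bundle = generate_bundle(cfg)
        a = bundle.dna_pileups["S1"].covered_sites(min_depth=1)
        b = bundle.dna_pileups["S2"].covered_sites(min_depth=1)
        rate = len(a & b) / len(b)
        assert 0.1 < rate < 0.55  # ~0.3 expected, generous run-level noise

    def test_editing_level_one_rna_pileup_fully_edited(self):
        cfg = SimConfig(seq_error_rate=0.0, editing_level=1.0, **TINY)
        bundle = generate_bundle(cfg)
        edits = {(r.chrom, r.pos): r.watson_rna_base
                 for r in bundle.editing.itertuples()}
        checked = 0
        for cell in cfg.oocyte_names:
            for col in bundle.rna[cell].pileup.iter_columns():
                target = edits.get((col.chrom, col.pos))
                if target is None:
                    continue
                assert col.base_count(target) == col.depth
                checked += 1
        assert checked > 0

    def test_crick_gene_editing_appears_as_t_to_c_in_genomic_pileup(self):
        bundle = generate_bundle(SimConfig(**TINY))
        crick = bundle.editing[bundle.editing["strand"] == "-"]
        if crick.empty:
            pytest.skip("no Crick-strand editing drawn in tiny bundle")
        assert (crick["watson_dna_base"] == "T").all()
        assert (crick["watson_rna_base"] == "C").all()


class TestEmitDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(**TINY)
        emit_dataset(cfg, tmp_path / "a")
        emit_dataset(cfg, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        (tmp_path / "x").mkdir()
        (tmp_path / "x" / "junk").write_text("hi")
        with pytest.raises(FileExistsError):
            emit_dataset(SimConfig(**TINY), tmp_path / "x")
        emit_dataset(SimConfig(**TINY), tmp_path / "x", force=True)

    def test_bundle_readable_end_to_end(self, tmp_path):
        """Emitted files parse with the package's own readers and the
        calls reproduce the in-memory analysis."""
        cfg = SimConfig(**TINY)
        bundle = emit_dataset(cfg, tmp_path / "d")
        with open(tmp_path / "d" / "annotation.gtf") as fh:
            models = read_gtf(fh)
        assert len(models) == len(bundle.transcripts)
        with open(tmp_path / "d" / "S1.dna.pileup") as fh:
            cols = list(read_pileup(fh))
        calls = call_sample(cols)
        direct = call_sample(bundle.dna_pileups["S1"].iter_columns())
        assert [c.status for c in calls] == [c.status for c in direct]
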