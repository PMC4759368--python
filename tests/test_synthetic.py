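"""Ground-truth fixture generator: determinism, placement, emitted files."""
import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from dhslink import annotation, io as dio, synthetic
from dhslink.synthetic import FixtureConfig, TruthSpec


def genome_signature(genome):
    return (
        tuple(genome.chroms.items()),
        tuple(
            (g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, g.exons)
            for g in genome.genes
        ),
    )


class TestMakeGenome:
    def test_empty_gene_case(self):
        g = synthetic.make_genome(1, 1_000_000, 0, seed=1)
        assert g.chroms == {"chr1": 1_000_000}
        assert g.genes == []

    def test_deterministic_for_fixed_seed(self):
        a = synthetic.make_genome(2, 1_000_000, 50, seed=7)
        b = synthetic.make_genome(2, 1_000_000, 50, seed=7)
        assert genome_signature(a) == genome_signature(b)

    def test_genes_within_bounds_with_exon_structure(self):
        g = synthetic.make_genome(1, 1_000_000, 50, seed=7)
        assert len(g.genes) == 50
        strands = set()
        for gene in g.genes:
            assert 0 <= gene.tx_start < gene.tx_end <= 1_000_000
            assert 2 <= len(gene.exons) <= 10
            strands.add(gene.strand)
        assert strands == {"+", "-"}

    def test_infeasible_density_fails_loudly(self):
        with pytest.raises(ValueError, match="density"):
            synthetic.make_genome(1, 100_000, 500, seed=1)


class TestMakeHotspotTruth:
    def test_no_unique_sites_identical_interval_lists(self):
        genome = synthetic.make_genome(1, 1_000_000, 20, seed=3)
        spec = TruthSpec(
            n_shared=30,
            n_unique={c: 0 for c in ("B34", "B39d1", "OIMd1")},
            n_planted_enhancers=0,
            seed=3,
        )
        truth = synthetic.make_hotspot_truth(genome, spec)
        lists = [
            [(s.chrom, s.start, s.end) for s in sites]
            for sites in truth.sites_by_condition.values()
        ]
        assert lists[0] == lists[1] == lists[2]

    def test_planted_enhancers_near_planted_genes_outside_promoters(self):
        genome = synthetic.make_genome(2, 1_000_000, 30, seed=5)
        spec = TruthSpec(n_planted_enhancers=10, seed=5)
        truth = synthetic.make_hotspot_truth(genome, spec)
        genes = {g.gene_id: g for g in genome.genes}
        index = annotation.GeneIndex(genome.genes)
        planted = [
            s for s in truth.sites_by_condition[spec.planted_condition]
            if s.planted_gene
        ]
        assert len(planted) == 10
        for s in planted:
            tss = genes[s.planted_gene].tss
            border = min(abs(tss - s.start), abs(tss - (s.end - 1)))
            if not (s.start <= tss < s.end):
                assert border <= 50_000
            assert not index.hits(index.promoters, s.chrom, s.start, s.end)
            assert s.category != "promoter"

    def test_fixed_seed_reproduces_truth(self):
        genome = synthetic.make_genome(1, 1_000_000, 20, seed=9)
        t1 = synthetic.make_hotspot_truth(genome, TruthSpec(seed=9))
        t2 = synthetic.make_hotspot_truth(genome, TruthSpec(seed=9))
        assert t1.sites_by_condition == t2.sites_by_condition

    def test_unknown_planted_gene_rejected(self):
        genome = synthetic.make_genome(1, 1_000_000, 5, seed=1)
        with pytest.raises(ValueError, match="planted"):
            synthetic.make_hotspot_truth(
                genome, TruthSpec(planted_genes=("NOPE",), seed=1)
            )


class TestSimulateTags:
    def test_single_site_raw_maxd_within_poisson_bound(self):
        genome = synthetic.make_genome(1, 200_000, 0, seed=1)
        site = synthetic.TrueSite(
            site_id="s", chrom="chr1", start=10_000, end=10_300,
            peak_pos=10_150, maxd=100.0, shared=True,
        )
        _track, (r1, r2) = synthetic.simulate_tags(
            [site], genome, total_reads=10_000_000, seed=4,
            background_fraction=0.0,
        )
        for rep in (r1, r2):
            assert abs(rep.sites[0].raw_maxd - 100) <= 4 * 10

    def test_zero_sites_zero_track_empty_calls(self):
        genome = synthetic.make_genome(1, 50_000, 0, seed=1)
        track, (r1, r2) = synthetic.simulate_tags(
            [], genome, total_reads=10_000, seed=2, background_fraction=0.0
        )
        assert not track["chr1"].any()
        assert len(r1) == 0 and len(r2) == 0

    def test_track_sum_close_to_library_size(self):
        genome = synthetic.make_genome(1, 100_000, 0, seed=1)
        sites = [
            synthetic.TrueSite(
                site_id=f"s{i}", chrom="chr1", start=1000 + 2000 * i,
                end=1300 + 2000 * i, peak_pos=1150 + 2000 * i,
                maxd=80.0, shared=True,
            )
            for i in range(10)
        ]
        total = 100_000
        track, _reps = synthetic.simulate_tags(sites, genome, total, seed=6)
        got = int(sum(t.sum() for t in track.values()))
        assert abs(got - total) < 6 * np.sqrt(total)

    def test_same_seed_identical_bedgraph_bytes(self, tmp_path):
        genome = synthetic.make_genome(1, 60_000, 0, seed=1)
        site = synthetic.TrueSite(
            site_id="s", chrom="chr1", start=5_000, end=5_200,
            peak_pos=5_100, maxd=50.0, shared=True,
        )
        blobs = []
        for k in range(2):
            track, _ = synthetic.simulate_tags([site], genome, 50_000, seed=8)
            path = tmp_path / f"t{k}.bedGraph"
            dio.write_bedgraph(track, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]


class TestSimulateExpression:
    def _genome(self):
        return synthetic.make_genome(1, 1_000_000, 30, seed=2)

    def test_dimensions(self):
        genome = self._genome()
        m = synthetic.simulate_expression(genome, ("G0001",), n_replicates=3,
                                          seed=1)
        assert m.shape == (30, 2 * 2 * 3)

    def test_zero_noise_effect_exactly_recovered(self):
        genome = self._genome()
        m = synthetic.simulate_expression(
            genome, ("G0003",), n_replicates=2, effect=2.0, noise_sd=0.0, seed=1
        )
        oim = m.filter(like="OIM:").loc["G0003"].mean()
        ctrl = m.filter(like="B39:").loc["G0003"].mean()
        assert np.log2(oim / ctrl) == pytest.approx(2.0, abs=1e-12)

    def test_null_effect_rarely_significant(self):
        from scipy import stats

        genome = self._genome()
        planted = ("G0000", "G0005", "G0010")
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            m = synthetic.simulate_expression(
                genome, planted, n_replicates=3, effect=0.0, noise_sd=0.25,
                seed=seed,
            )
            sub = np.log2(m.loc[list(planted)])
            oim = sub.filter(like="OIM:").to_numpy().ravel()
            ctrl = sub.filter(like="B39:").to_numpy().ravel()
            if stats.ttest_ind(oim, ctrl).pvalue < 0.01:
                hits += 1
        assert n_runs - hits >= 95


class TestWriteFixture:
    def test_manifest_truth_and_gmt_round_trip(self, tmp_path, small_config):
        fx = synthetic.generate_fixture(seed=21, config=small_config)
        manifest = synthetic.write_fixture(fx, tmp_path)
        assert len(manifest) >= 8
        truth = dio.read_json(tmp_path / "truth.json")
        assert truth == synthetic.truth_to_dict(fx.truth)
        gmt = dio.read_gmt(tmp_path / "sets.gmt")
        assert synthetic.PLANTED_SET_NAME in gmt
        assert gmt[synthetic.PLANTED_SET_NAME] == set(fx.truth.planted_genes)

    def test_emitted_beds_match_truth_counts(self, tmp_path, small_config):
        fx = synthetic.generate_fixture(seed=22, config=small_config)
        synthetic.write_fixture(fx, tmp_path)
        spec = fx.truth.spec
        for cond in spec.conditions:
            hset = dio.read_hotspots_bed(
                tmp_path / f"hotspots_{cond}_rep1.bed", "x", cond,
                fx.config.total_reads,
            )
            # brute-force recount of unique vs shared site ids in the BED
            n_shared = sum(1 for h in hset.sites
                           if h.site_id.startswith("shared_"))
            n_unique = len(hset.sites) - n_shared
            assert n_shared == fx.truth.shared_count()
            assert n_unique == fx.truth.unique_counts()[cond]

    def test_fixed_seed_byte_identical_directory(self, tmp_path, small_config):
        import copy

        digests = []
        for run in range(2):
            out = tmp_path / f"run{run}"
            fx = synthetic.generate_fixture(
                seed=33, config=copy.deepcopy(small_config)
            )
            manifest = synthetic.write_fixture(fx, out)
            h = hashlib.sha256()
            for name in sorted(manifest):
                h.update(name.encode())
                h.update((out / name).read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]
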