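"""Step inference, rank-window neighborhoods, SusD evidence tiers and scanning."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulcensus import vicinity as vic
from pulcensus.errors import InsufficientDataError, LookupError_, StateError
from pulcensus.io import Dataset, DomainHit
from pulcensus.synthetic import GeneratorConfig, expected_scan, generate

from conftest import make_gene


def genome_dataset(indices, genome="g01"):
    genes = {}
    for i in indices:
        gid = f"{genome}:{i:05d}"
        genes[gid] = make_gene(gid, index=i)
    return Dataset(genes=genes, provenance="test")


class TestInferStep:
    @pytest.mark.parametrize(
        "indices,step,regular",
        [
            ([5, 10, 15, 20, 25], 5, True),
            ([1, 2, 3, 4], 1, True),
            ([10, 20, 30, 50, 60], 10, False),  # mode of diffs {10,10,20,10}
            ([1, 2, 4, 5, 7, 8], 1, False),  # tie 1 vs 2/3: smaller wins
        ],
    )
    def test_mode_of_consecutive_differences(self, indices, step, regular):
        m = vic.infer_step(indices, "g")
        assert (m.step, m.regular) == (step, regular)

    def test_single_index_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            vic.infer_step([5])

    @pytest.mark.parametrize("step", [1, 5, 10])
    def test_recovers_planted_step_on_gap_free_genomes(self, step):
        rng = random.Random(step)
        for _ in range(100):
            n = rng.randrange(5, 60)
            start = rng.randrange(1, 50) * step
            m = vic.infer_step([start + k * step for k in range(n)])
            assert m.step == step and m.regular


class TestNeighbors:
    def test_full_window_coverage(self):
        ds = genome_dataset(range(10, 111, 10))
        nbrs = vic.neighbors(ds, "g01:00060", w=5)
        assert len(nbrs) == 10
        assert "g01:00060" not in nbrs

    def test_edge_truncation_downstream_only(self):
        ds = genome_dataset(range(10, 111, 10))
        nbrs = vic.neighbors(ds, "g01:00010", w=5)
        assert nbrs == [f"g01:{i:05d}" for i in range(20, 70, 10)]

    def test_unknown_target_is_lookup_error(self):
        ds = genome_dataset([1, 2, 3])
        with pytest.raises(LookupError_):
            vic.neighbors(ds, "g01:00099")

    def test_matches_dual_oracles_on_random_genomes(self):
        """Rank-window oracle on gapped genomes; index arithmetic must agree
        on regular ones."""
        rng = random.Random(11)
        for _ in range(120):
            step = rng.choice([1, 5, 10])
            gap_rate = rng.choice([0.0, 0.1, 0.2])
            indices, nxt = [], step
            for _ in range(rng.randrange(8, 40)):
                if indices and rng.random() < gap_rate:
                    nxt += step
                indices.append(nxt)
                nxt += step
            ds = genome_dataset(indices)
            w = rng.randrange(1, 7)
            target_i = rng.choice(indices)
            target = f"g01:{target_i:05d}"

            got = vic.neighbors(ds, target, w)
            # oracle 1: sort indices, take ranks +-w
            r = sorted(indices).index(target_i)
            expect = [
                f"g01:{sorted(indices)[k]:05d}"
                for k in range(max(0, r - w), min(len(indices), r + w + 1))
                if k != r
            ]
            assert got == expect
            # oracle 2: index arithmetic target +- k*step on regular genomes
            if gap_rate == 0.0:
                by_index = {
                    f"g01:{target_i + k * step:05d}"
                    for k in range(-w, w + 1)
                    if k != 0 and target_i + k * step in set(indices)
                }
                assert set(got) == by_index


class TestSusdEvidence:
    def test_ko_wins_over_everything(self):
        g = make_gene("g01:00010", ko="K21572", annotation="hypothetical protein")
        assert vic.susd_evidence(g).tier == vic.TIER_ID

    def test_domain_annotation_tier(self):
        g = make_gene("g01:00010")
        hits = [DomainHit("g01:00010", "SusD-like domain", 10, 400, 1e-30)]
        ev = vic.susd_evidence(g, hits)
        assert ev.tier == vic.TIER_D and "SusD-like" in ev.matched_text

    def test_name_annotation_tier(self):
        g = make_gene("g01:00010", annotation="RagB/SusD family protein")
        assert vic.susd_evidence(g).tier == vic.TIER_N

    def test_no_evidence(self):
        assert vic.susd_evidence(make_gene("g01:00010")).tier == vic.TIER_NONE

    def test_matching_is_case_insensitive_substring(self):
        g = make_gene("g01:00010", annotation="putative SUSD   homolog")
        assert vic.susd_evidence(g).tier == vic.TIER_N

    def test_adding_ko_only_upgrades(self):
        """Tier precedence: a K21572 KO upgrades any D/N gene, never downgrades."""
        order = [vic.TIER_ID, vic.TIER_D, vic.TIER_N, vic.TIER_NONE]
        for base in (
            make_gene("g01:00010", annotation="RagB/SusD family protein"),
            make_gene("g01:00010"),
        ):
            before = vic.susd_evidence(base).tier
            upgraded = make_gene("g01:00010", ko="K21572",
                                 annotation=base.annotation)
            after = vic.susd_evidence(upgraded).tier
            assert order.index(after) <= order.index(before)


class TestScan:
    def test_planted_susd_found_at_offset(self, small_dataset):
        ds, target, susd, _ = small_dataset
        results, summary = vic.scan(ds, "DUF1735", w=5)
        (r,) = results
        assert r.target_gene_id == target
        assert r.pul_positive
        assert r.susd_hit.gene_id == susd
        assert r.susd_hit.offset == -1
        assert r.susd_hit.tier == vic.TIER_ID
        assert summary.n_pul_positive == 1

    def test_susd_outside_window_is_negative(self, small_dataset):
        ds, target, _, _ = small_dataset
        results, summary = vic.scan(ds, "DUF1735", w=5)
        assert results[0].pul_positive
        # shrink the window below the offset: no longer positive
        results0, _ = vic.scan(ds, "DUF1735", w=0)
        assert not results0[0].pul_positive

    def test_unknown_domain_is_empty_not_error(self, small_dataset):
        ds, *_ = small_dataset
        results, summary = vic.scan(ds, "NoSuchDomain")
        assert results == [] and summary.n_targets == 0

    def test_fraction_equals_manifest_plant(self):
        cfg = GeneratorConfig(n_genomes=5, genes_per_genome=64, n_planted=9,
                              n_decoys=1)
        ds, man = generate(cfg, seed=3)
        _, summary = vic.scan(ds, "DUF1735")
        assert summary.fraction == man.pul_positive_fraction == 0.9
        assert summary.tier_counts == man.tier_counts()

    def test_window_monotonicity(self):
        ds, _ = generate(GeneratorConfig(n_genomes=4, genes_per_genome=64,
                                         n_planted=6, n_decoys=2), seed=5)
        positive = {}
        for w in (1, 3, 5):
            results, _ = vic.scan(ds, "DUF1735", w=w)
            positive[w] = {r.target_gene_id for r in results if r.pul_positive}
        assert positive[1] <= positive[3] <= positive[5]

    def test_gene_level_result_carries_copy_count(self):
        ds, man = generate(GeneratorConfig(n_genomes=4, genes_per_genome=64,
                                           n_planted=6, n_decoys=0), seed=9)
        results, _ = vic.scan(ds, "DUF1735")
        by_gene = {r.target_gene_id: r for r in results}
        for p in man.planted:
            assert by_gene[p.target_gene_id].n_domain_copies == p.n_domain_copies

    def test_best_tier_then_distance_then_upstream(self):
        genes, hits = {}, []
        for i in range(1, 12):
            gid = f"g01:{i:05d}"
            genes[gid] = make_gene(gid, index=i)
        target = "g01:00006"
        hits.append(DomainHit(target, "DUF1735", 25, 140, 1e-9))
        # tier-N neighbor adjacent, tier-ID neighbor farther: ID wins
        genes["g01:00005"] = make_gene("g01:00005",
                                       annotation="RagB/SusD family protein")
        genes["g01:00009"] = make_gene("g01:00009", ko="K21572")
        ds = Dataset(genes=genes, hits=hits)
        results, _ = vic.scan(ds, "DUF1735")
        assert results[0].susd_hit.gene_id == "g01:00009"
        # equal tier both sides at same distance: upstream (negative) wins
        genes["g01:00003"] = make_gene("g01:00003", ko="K21572")
        ds2 = Dataset(genes=dict(genes), hits=list(hits))
        results2, _ = vic.scan(ds2, "DUF1735")
        assert results2[0].susd_hit.offset == -3


class TestClassifyPosition:
    @pytest.mark.parametrize("d,expected",
                             [(1, "susE-like"), (2, "susF-like"),
                              (3, "susG-like"), (4, "other")])
    def test_downstream_distance_maps_to_class(self, d, expected):
        genes, hits = {}, []
        for i in range(1, 13):
            gid = f"g01:{i:05d}"
            genes[gid] = make_gene(gid, index=i)
        genes["g01:00003"] = make_gene("g01:00003", ko="K21573",
                                       annotation="SusC-like transporter")
        genes["g01:00004"] = make_gene("g01:00004", ko="K21572")
        target = f"g01:{4 + d:05d}"
        hits.append(DomainHit(target, "DUF1735", 25, 140, 1e-9))
        ds = Dataset(genes=genes, hits=hits)
        results, _ = vic.scan(ds, "DUF1735")
        assert results[0].position_class == expected

    def test_upstream_of_pair_is_other(self):
        genes, hits = {}, []
        for i in range(1, 13):
            gid = f"g01:{i:05d}"
            genes[gid] = make_gene(gid, index=i)
        # pair susD(6)/susC(7): target at 4 is on the susD side but upstream
        genes["g01:00006"] = make_gene("g01:00006", ko="K21572")
        genes["g01:00007"] = make_gene("g01:00007", ko="K21573",
                                       annotation="SusC-like transporter")
        hits.append(DomainHit("g01:00004", "DUF1735", 25, 140, 1e-9))
        ds = Dataset(genes=genes, hits=hits)
        results, _ = vic.scan(ds, "DUF1735")
        # susC at rank+1 flips downstream to decreasing rank: d=2 -> susF-like
        assert results[0].position_class == "susF-like"
        # without a susC, increasing rank is downstream: upstream target -> other
        del genes["g01:00007"]
        genes["g01:00007"] = make_gene("g01:00007", index=7)
        ds2 = Dataset(genes=genes, hits=hits)
        results2, _ = vic.scan(ds2, "DUF1735")
        assert results2[0].position_class == "other"

    def test_pul_negative_is_state_error(self):
        r = vic.VicinityResult("g:1", 5, (), None)
        with pytest.raises(StateError):
            vic.classify_position(r, Dataset())


class TestOracleEquivalence:
    def test_scan_matches_brute_force_over_seeds(self):
        cfg = GeneratorConfig(n_genomes=6, genes_per_genome=64, n_planted=10,
                              n_decoys=2)
        for seed in range(10):
            ds, man = generate(cfg, seed=seed)
            results, summary = vic.scan(ds, "DUF1735")
            exp = expected_scan(ds, man, 5)
            assert summary.n_targets == exp.n_targets
            assert summary.n_pul_positive == exp.n_pul_positive
            assert summary.tier_counts == exp.tier_counts
            got = {
                r.target_gene_id: (r.susd_hit.gene_id, r.susd_hit.tier,
                                   r.susd_hit.offset)
                for r in results
                if r.pul_positive
            }
            assert got == exp.positives
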