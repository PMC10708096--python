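import numpy as np
import pytest

from conftest import random_matrix
from oracles import brute_force_gamete_ss
from snpdiv.amova_fst import (
    _gamete_matrix,
    amova,
    pairwise_fst,
    weir_cockerham_fst,
)
from snpdiv.io_formats import GenotypeMatrix
from snpdiv.synthetic_data import SimulationConfig, simulate


def _fixed_groups_matrix(n_per=4, l=6):
    """Two groups fixed for opposite alleles at every locus."""
    dosage = np.vstack(
        [np.zeros((n_per, l), dtype=np.int8), np.full((n_per, l), 2, dtype=np.int8)]
    )
    ids = [f"a{i}" for i in range(2 * n_per)]
    g = GenotypeMatrix(ids, [f"L{j}" for j in range(l)], dosage)
    grouping = {aid: ("A" if i < n_per else "B") for i, aid in enumerate(ids)}
    return g, grouping


def _split_one_population(seed):
    cfg = SimulationConfig(
        k_true=1, drift_f=0.05, n_accessions=40, n_loci=50,
        admixture_alpha=0.0, seed=seed,
    )
    g, _, _ = simulate(cfg)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(g.n_accessions)
    grouping = {
        g.accession_ids[i]: ("A" if rank < 20 else "B") for rank, i in enumerate(perm)
    }
    return g, grouping


class TestAmova:
    def test_df_sum_to_2n_minus_1(self, fixture_dataset):
        g, metadata, _ = fixture_dataset
        grouping = {rec.name: rec.maturation for rec in metadata}
        res = amova(g, grouping, n_permutations=9, seed=0)
        assert sum(res.df.values()) == 2 * g.n_accessions - 1

    def test_fully_fixed_groups(self):
        g, grouping = _fixed_groups_matrix()
        res = amova(g, grouping, n_permutations=9, seed=0)
        assert res.pct_variation["among_populations"] == pytest.approx(100.0)
        assert res.pct_variation["within_individuals"] == pytest.approx(0.0)
        assert res.pct_variation["among_individuals_within_populations"] == pytest.approx(0.0)

    def test_ss_partition_identity_brute_force(self):
        rng = np.random.default_rng(77)
        g = random_matrix(rng, 6, 4, missing_rate=0.1)
        grouping = {aid: ("A" if i < 3 else "B") for i, aid in enumerate(g.accession_ids)}
        res = amova(g, grouping, n_permutations=9, seed=1)
        gam = _gamete_matrix(g)
        groups = [[2 * i, 2 * i + 1] for i in range(3)], [[2 * i, 2 * i + 1] for i in range(3, 6)]
        flat = [sorted(x for pair in grp for x in pair) for grp in groups]
        ss_total, ss_ap, ss_ai, ss_wi = brute_force_gamete_ss(gam, g.n_loci, flat)
        assert res.ss["among_populations"] == pytest.approx(ss_ap, abs=1e-9)
        assert res.ss["among_individuals_within_populations"] == pytest.approx(ss_ai, abs=1e-9)
        assert res.ss["within_individuals"] == pytest.approx(ss_wi, abs=1e-9)
        assert res.total_ss == pytest.approx(ss_total, abs=1e-9)

    @pytest.mark.parametrize("seed", [101, 202])
    def test_ss_partition_identity_random(self, seed):
        rng = np.random.default_rng(seed)
        g = random_matrix(rng, 10, 8, missing_rate=0.05)
        grouping = {aid: ("A" if i % 2 else "B") for i, aid in enumerate(g.accession_ids)}
        res = amova(g, grouping, n_permutations=5, seed=0)
        gam = _gamete_matrix(g)
        members = {lab: [] for lab in ("A", "B")}
        for i, aid in enumerate(g.accession_ids):
            members[grouping[aid]].extend([2 * i, 2 * i + 1])
        ss_total, ss_ap, ss_ai, ss_wi = brute_force_gamete_ss(
            gam, g.n_loci, [members["A"], members["B"]]
        )
        assert res.total_ss == pytest.approx(ss_total, abs=1e-9)
        assert res.ss["among_populations"] == pytest.approx(ss_ap, abs=1e-9)

    def test_null_split_calibration(self):
        pcts, pvals = [], []
        for seed in range(10):
            g, grouping = _split_one_population(3000 + seed)
            res = amova(g, grouping, n_permutations=99, seed=seed)
            pcts.append(res.pct_variation["among_populations"])
            pvals.append(res.p_values["among_populations"])
        assert all(p <= 3.0 for p in pcts)  # among-group pct ~ 0 within +3%
        assert sum(p >= 0.05 for p in pvals) >= 8

    def test_group_of_size_one_error(self):
        rng = np.random.default_rng(0)
        g = random_matrix(rng, 4, 5, missing_rate=0.0)
        grouping = {aid: ("A" if i else "B") for i, aid in enumerate(g.accession_ids)}
        with pytest.raises(ValueError):
            amova(g, grouping, n_permutations=9, seed=0)

    def test_permutation_reproducibility_and_label_invariance(self):
        rng = np.random.default_rng(55)
        g = random_matrix(rng, 12, 10, missing_rate=0.0)
        grouping = {aid: ("A" if i < 6 else "B") for i, aid in enumerate(g.accession_ids)}
        renamed = {aid: ("zzz" if v == "A" else "aaa") for aid, v in grouping.items()}
        r1 = amova(g, grouping, n_permutations=49, seed=9)
        r2 = amova(g, grouping, n_permutations=49, seed=9)
        r3 = amova(g, renamed, n_permutations=49, seed=9)
        assert r1.p_values == r2.p_values
        assert r1.ss["among_populations"] == pytest.approx(r3.ss["among_populations"])


class TestPairwiseFst:
    def test_fixed_groups_fst_one(self):
        g, grouping = _fixed_groups_matrix()
        res = pairwise_fst(g, grouping, n_permutations=9, seed=0)
        assert res.fst[0, 1] == pytest.approx(1.0)

    def test_identical_duplicated_groups_near_zero(self):
        vals = []
        for seed in range(10):
            cfg = SimulationConfig(
                k_true=2, drift_f=0.3, n_accessions=84, n_loci=91,
                admixture_alpha=1.0, seed=6000 + seed,
            )
            g, _, _ = simulate(cfg)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(g.n_accessions)
            grouping = {
                g.accession_ids[i]: ("A" if rank % 2 else "B")
                for rank, i in enumerate(perm)
            }
            res = pairwise_fst(g, grouping, n_permutations=1, seed=seed)
            vals.append(res.fst[0, 1])
        assert all(abs(v) < 0.02 for v in vals)

    def test_monotone_in_simulation_drift(self):
        means = {}
        for f in (0.05, 0.30):
            vals = []
            for seed in range(10):
                cfg = SimulationConfig(
                    k_true=2, drift_f=f, n_accessions=40, n_loci=50,
                    admixture_alpha=0.0, seed=8000 + seed,
                )
                g, _, truth = simulate(cfg)
                grouping = {
                    aid: str(int(np.argmax(truth.q_true[i])))
                    for i, aid in enumerate(g.accession_ids)
                }
                res = pairwise_fst(g, grouping, n_permutations=1, seed=seed)
                vals.append(res.fst[0, 1])
            means[f] = np.mean(vals)
        assert means[0.30] > means[0.05]

    def test_directional_ordering_three_populations(self):
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(
                k_true=3, drift_f=(0.05, 0.05, 0.5), n_accessions=45, n_loci=60,
                admixture_alpha=0.0, seed=9000 + seed,
            )
            g, _, truth = simulate(cfg)
            grouping = {
                aid: "ABC"[int(np.argmax(truth.q_true[i]))]
                for i, aid in enumerate(g.accession_ids)
            }
            res = pairwise_fst(g, grouping, n_permutations=1, seed=seed)
            labels = res.labels
            a, b, c = labels.index("A"), labels.index("B"), labels.index("C")
            if res.fst[a, c] > res.fst[a, b]:
                wins += 1
        assert wins >= 9

    def test_symmetry_and_diagonal(self, two_pop_dataset):
        g, _, truth = two_pop_dataset
        grouping = {
            aid: str(int(np.argmax(truth.q_true[i])))
            for i, aid in enumerate(g.accession_ids)
        }
        res = pairwise_fst(g, grouping, n_permutations=9, seed=0)
        assert res.fst[0, 1] == res.fst[1, 0]
        assert np.isnan(res.fst[0, 0])


class TestWeirCockerham:
    def test_fixed_groups(self):
        g, grouping = _fixed_groups_matrix()
        assert weir_cockerham_fst(g, grouping) == pytest.approx(1.0)

    def test_agrees_in_direction_with_distance_fst(self, two_pop_dataset):
        g, _, truth = two_pop_dataset
        grouping = {
            aid: str(int(np.argmax(truth.q_true[i])))
            for i, aid in enumerate(g.accession_ids)
        }
        theta = weir_cockerham_fst(g, grouping)
        res = pairwise_fst(g, grouping, n_permutations=1, seed=0)
        assert theta > 0.1
        assert res.fst[0, 1] > 0.1
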