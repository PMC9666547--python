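"""Ensemble/two-order averaging, contact conversion, ranking, confidence."""

import numpy as np
import pytest

from dimerdist import infer
from dimerdist.infer import ContactScoreMap
from dimerdist.nn.model import DistogramPrediction


def _random_prediction(side, rng, lengths=None, kind="homodimer"):
    vols = []
    for _ in range(2):
        v = rng.uniform(size=(side, side, 42))
        v /= v.sum(axis=-1, keepdims=True)
        vols.append(v.astype(np.float32))
    return DistogramPrediction(
        heavy_atom_probs=vols[0],
        cb_probs=vols[1],
        lengths=lengths or (side, side),
        dimer_kind=kind,
    )


def _one_hot_prediction(side, bin_index, lengths=None, kind="homodimer"):
    v = np.zeros((side, side, 42), dtype=np.float32)
    v[:, :, bin_index] = 1.0
    return DistogramPrediction(
        heavy_atom_probs=v, cb_probs=v.copy(), lengths=lengths or (side, side),
        dimer_kind=kind,
    )


class TestAverageEnsemble:
    def test_idempotent_on_identical_members(self):
        rng = np.random.default_rng(0)
        p = _random_prediction(4, rng)
        avg = infer.average_ensemble([p, p])
        np.testing.assert_allclose(avg.heavy_atom_probs, p.heavy_atom_probs, atol=1e-7)

    def test_mean_of_opposite_one_hots(self):
        avg = infer.average_ensemble(
            [_one_hot_prediction(2, 0), _one_hot_prediction(2, 41)]
        )
        assert avg.heavy_atom_probs[0, 0, 0] == pytest.approx(0.5)
        assert avg.heavy_atom_probs[0, 0, 41] == pytest.approx(0.5)

    def test_cells_stay_normalized(self):
        rng = np.random.default_rng(1)
        avg = infer.average_ensemble([_random_prediction(5, rng) for _ in range(3)])
        np.testing.assert_allclose(avg.heavy_atom_probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="shape mismatch"):
            infer.average_ensemble(
                [_random_prediction(3, rng), _random_prediction(4, rng)]
            )


class TestAverageTwoOrders:
    def _swap(self, pred, l1, l2):
        perm = np.concatenate([np.arange(l1, l1 + l2), np.arange(l1)])
        return DistogramPrediction(
            heavy_atom_probs=pred.heavy_atom_probs[np.ix_(perm, perm)],
            cb_probs=pred.cb_probs[np.ix_(perm, perm)],
            lengths=(l2, l1),
            dimer_kind="heterodimer",
        )

    def test_exact_index_swap_recovers_ab_block(self):
        # a physically consistent dimer map is mirror-symmetric (d_ij = d_ji),
        # and then transposing the swapped order's block cancels the swap
        rng = np.random.default_rng(0)
        l1, l2 = 3, 4
        raw = _random_prediction(l1 + l2, rng, lengths=(l1, l2), kind="heterodimer")
        sym_heavy = 0.5 * (raw.heavy_atom_probs + raw.heavy_atom_probs.transpose(1, 0, 2))
        sym_cb = 0.5 * (raw.cb_probs + raw.cb_probs.transpose(1, 0, 2))
        pred_ab = DistogramPrediction(
            heavy_atom_probs=sym_heavy, cb_probs=sym_cb, lengths=(l1, l2),
            dimer_kind="heterodimer",
        )
        pred_ba = self._swap(pred_ab, l1, l2)
        out = infer.average_two_orders(pred_ab, pred_ba, l1, l2)
        np.testing.assert_array_equal(
            out["heavy_atom_probs"], pred_ab.heavy_atom_probs[:l1, l1:]
        )

    def test_one_by_one_toy_is_plain_mean(self):
        rng = np.random.default_rng(1)
        ab = _random_prediction(2, rng, lengths=(1, 1), kind="heterodimer")
        ba = _random_prediction(2, rng, lengths=(1, 1), kind="heterodimer")
        out = infer.average_two_orders(ab, ba, 1, 1)
        expected = 0.5 * (ab.heavy_atom_probs[0, 1] + ba.heavy_atom_probs[0, 1])
        np.testing.assert_allclose(out["heavy_atom_probs"][0, 0], expected, atol=1e-7)

    def test_output_shape_and_normalization(self):
        rng = np.random.default_rng(2)
        l1, l2 = 2, 5
        ab = _random_prediction(7, rng, lengths=(l1, l2), kind="heterodimer")
        ba = _random_prediction(7, rng, lengths=(l2, l1), kind="heterodimer")
        out = infer.average_two_orders(ab, ba, l1, l2)
        assert out["heavy_atom_probs"].shape == (l1, l2, 42)
        np.testing.assert_allclose(
            out["heavy_atom_probs"].sum(axis=-1), 1.0, atol=1e-6
        )

    def test_argument_swap_transposes_output(self):
        rng = np.random.default_rng(3)
        l1, l2 = 3, 2
        ab = _random_prediction(5, rng, lengths=(l1, l2), kind="heterodimer")
        ba = _random_prediction(5, rng, lengths=(l2, l1), kind="heterodimer")
        out = infer.average_two_orders(ab, ba, l1, l2)
        swapped = infer.average_two_orders(ba, ab, l2, l1)
        np.testing.assert_allclose(
            out["heavy_atom_probs"], swapped["heavy_atom_probs"].transpose(1, 0, 2),
            atol=1e-7,
        )


class TestContactProbability:
    def test_mass_in_first_bin(self):
        cell = np.zeros(42)
        cell[0] = 1.0
        assert infer.contact_probability(cell) == pytest.approx(1.0)

    def test_mass_in_last_bin(self):
        cell = np.zeros(42)
        cell[41] = 1.0
        assert infer.contact_probability(cell) == pytest.approx(0.0)

    def test_straddling_the_eight_angstrom_edge(self):
        cell = np.zeros(42)
        cell[12] = 0.5  # [7.5, 8)
        cell[13] = 0.5  # [8, 8.5)
        assert infer.contact_probability(cell, 8.0) == pytest.approx(0.5)

    def test_non_boundary_threshold_interpolates(self):
        cell = np.zeros(42)
        cell[13] = 1.0  # [8, 8.5)
        assert infer.contact_probability(cell, 8.25) == pytest.approx(0.5)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        cell = rng.uniform(size=42)
        cell /= cell.sum()
        probs = [infer.contact_probability(cell, t) for t in np.arange(0.5, 22.01, 0.25)]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            infer.contact_probability(np.ones(42) / 42, 25.0)


class TestRankContacts:
    def test_homodimer_dedupe_merges_mirror_pairs(self):
        scores = ContactScoreMap(
            scores=np.array([[0.1, 0.9], [0.9, 0.2]]), dimer_kind="homodimer"
        )
        ranked = infer.rank_contacts(scores, dedupe_symmetric=True)
        assert len(ranked) == 3
        assert ranked.entries[0] == (1, 2, 0.9)

    def test_tie_break_is_lexicographic(self):
        scores = ContactScoreMap(scores=np.full((2, 2), 0.5), dimer_kind="heterodimer")
        ranked = infer.rank_contacts(scores, dedupe_symmetric=False)
        assert [(i, j) for i, j, _ in ranked.entries] == [
            (1, 1), (1, 2), (2, 1), (2, 2),
        ]

    def test_heterodimer_has_all_pairs(self):
        rng = np.random.default_rng(0)
        scores = ContactScoreMap(scores=rng.uniform(size=(2, 3)), dimer_kind="heterodimer")
        assert len(infer.rank_contacts(scores, dedupe_symmetric=False)) == 6


class TestConfidence:
    def test_mean_of_top_fifth(self):
        from dimerdist.structio import RankedContactList

        rc = RankedContactList(entries=[(1, 1, 0.8), (1, 2, 0.6), (2, 1, 0.4)])
        assert infer.confidence_score(rc, 10) == pytest.approx(0.7)

    def test_constant_probabilities(self):
        from dimerdist.structio import RankedContactList

        rc = RankedContactList(entries=[(1, 1, 0.3)] * 5)
        assert infer.confidence_score(rc, 25) == pytest.approx(0.3)

    def test_raising_a_top_probability_never_lowers_score(self):
        from dimerdist.structio import RankedContactList

        base = [(1, 1, 0.8), (1, 2, 0.6), (2, 1, 0.4), (2, 2, 0.2)]
        up = [(1, 1, 0.9), (1, 2, 0.6), (2, 1, 0.4), (2, 2, 0.2)]
        s0 = infer.confidence_score(RankedContactList(entries=base), 10)
        s1 = infer.confidence_score(RankedContactList(entries=up), 10)
        assert s1 >= s0

    def test_empty_list_rejected(self):
        from dimerdist.structio import RankedContactList

        with pytest.raises(ValueError, match="empty"):
            infer.confidence_score(RankedContactList(entries=[]), 10)


class TestSymmetrization:
    def test_homodimer_score_map_exactly_symmetric(self):
        rng = np.random.default_rng(0)
        pred = _random_prediction(6, rng, kind="homodimer")
        scores = infer.contact_map_from_distogram(pred, symmetrize_output=True)
        np.testing.assert_array_equal(scores.scores, scores.scores.T)

    def test_heterodimer_block_extraction(self):
        rng = np.random.default_rng(1)
        pred = _random_prediction(5, rng, lengths=(2, 3), kind="heterodimer")
        scores = infer.contact_map_from_distogram(pred)
        assert scores.shape == (2, 3)
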