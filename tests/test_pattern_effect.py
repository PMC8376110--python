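"""EPE/DEPE estimators: insertion, identities, antisymmetry, screens."""

import numpy as np
import pandas as pd
import pytest

import motifeffect as me
from motifeffect import pattern_effect as pe
from motifeffect.genomic_io import LabeledDataset
from motifeffect.model import build_ensemble
from motifeffect.motifs import PWM, Pattern
from motifeffect.synthetic import pwm_from_consensus


def tiny_ensemble(seed=0, n_classes=2, L=30):
    cfg = me.ModelConfig(
        window_length=L, n_classes=n_classes,
        class_names=[f"c{i+1}" for i in range(n_classes)],
        ensemble_size=2, first_layer=(4, 5),
        member_second_layers=[(3, 3), (5, 4)], seed=seed,
    )
    return build_ensemble(cfg)


def constant_ensemble(**kw):
    ens = tiny_ensemble(**kw)
    for m in ens.members:
        for p in m.params:
            p[...] = 0.0  # zero logits -> every prediction exactly 0.5
    return ens


def identical_head_ensemble(**kw):
    ens = tiny_ensemble(**kw)
    for m in ens.members:
        m.W3[:, 1] = m.W3[:, 0]
        m.b3[1] = m.b3[0]
    return ens


@pytest.fixture()
def backgrounds(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
    return pe.BackgroundSet(seqs, source="synthetic", seed=0)


class TestInsertPattern:
    def test_default_position_is_centered(self):
        out = pe.insert_pattern("AAAAAAAAAA", Pattern("p", "CGT"))
        assert out == "AAACGTAAAA"

    def test_wildcards_keep_background(self):
        out = pe.insert_pattern("AAAAAAAAAA", Pattern("p", "C**G"), position=2)
        assert out == "AACAAGAAAA"

    def test_length_preserved(self, rng):
        bg = "".join(rng.choice(list("ACGT"), 25))
        assert len(pe.insert_pattern(bg, Pattern("p", "TTGT***ATGCAA"))) == 25

    def test_oversized_pattern_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            pe.insert_pattern("A" * 10, Pattern("p", "C" * 11))

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="position"):
            pe.insert_pattern("A" * 10, Pattern("p", "CCC"), position=8)


class TestEPE:
    def test_identity_pattern_gives_alpha_one_exactly(self, backgrounds):
        ens = tiny_ensemble()
        for seq in backgrounds.sequences:
            center = (len(seq) - 8) // 2
            pat = Pattern("self", seq[center:center + 8])
            pair = pe.BackgroundSet([seq, seq], source="synthetic")
            r = pe.epe(ens, pair, pat, "c1")
            assert r.alpha == 1.0 and r.W == 0.0 and r.p_value == 1.0

    def test_constant_model_gives_alpha_one(self, backgrounds):
        ens = constant_ensemble()
        r = pe.epe(ens, backgrounds, Pattern("p", "TGACTCAG"), "c1")
        assert r.alpha == 1.0 and r.W == 0.0 and r.p_value == 1.0

    def test_alpha_positive_and_w_bounded(self, backgrounds):
        ens = tiny_ensemble(seed=3)
        r = pe.epe(ens, backgrounds, Pattern("p", "TGACTCAG"), "c1")
        assert r.alpha > 0
        assert abs(r.W) <= (r.M + 1) / 2
        assert r.p_adjusted >= r.p_value

    def test_clipping_epsilon_is_inert_for_moderate_predictions(
        self, backgrounds, monkeypatch
    ):
        ens = tiny_ensemble(seed=4)  # untrained: predictions near 0.5
        pat = Pattern("p", "TGACTCAG")
        r1 = pe.epe(ens, backgrounds, pat, "c1")
        monkeypatch.setattr(pe, "EPS", pe.EPS / 10)
        r2 = pe.epe(ens, backgrounds, pat, "c1")
        assert r1.alpha == r2.alpha and r1.W == r2.W and r1.p_value == r2.p_value

    def test_both_strands_takes_per_background_max(self, backgrounds):
        ens = tiny_ensemble(seed=5)
        pat = Pattern("p", "TTGACA")
        fwd = pe.epe(ens, backgrounds, pat, "c1")
        rc = pe.epe(ens, backgrounds, pat.reverse_complement(), "c1")
        both = pe.epe(ens, backgrounds, pat, "c1", both_strands=True)
        expected = np.maximum(2.0 ** fwd.log2_ratios, 2.0 ** rc.log2_ratios).mean()
        assert both.alpha == pytest.approx(expected)
        assert both.alpha >= max(fwd.alpha, rc.alpha) - 1e-12


class TestDEPE:
    def test_antisymmetry_and_equal_p(self, backgrounds):
        ens = tiny_ensemble(seed=6)
        pat = Pattern("p", "CACGTGAC")
        fwd = pe.depe(ens, backgrounds, pat, "c1", "c2")
        rev = pe.depe(ens, backgrounds, pat, "c2", "c1")
        assert fwd.depe == pytest.approx(-rev.depe, abs=1e-10)
        assert fwd.p_value == rev.p_value
        assert fwd.W == pytest.approx(-rev.W)

    def test_identical_heads_give_zero_everywhere(self, backgrounds):
        ens = identical_head_ensemble()
        r = pe.depe(ens, backgrounds, Pattern("p", "CACGTGAC"), "c1", "c2")
        assert r.depe == 0.0 and r.W == 0.0 and r.p_value == 1.0

    def test_same_class_rejected(self, backgrounds):
        with pytest.raises(ValueError, match="distinct"):
            pe.depe(tiny_ensemble(), backgrounds, Pattern("p", "ACGT"), "c1", "c1")

    def test_consistency_with_per_class_epe_log_ratios(self, backgrounds):
        ens = tiny_ensemble(seed=7)
        pat = Pattern("p", "TGACTCAG")
        d = pe.depe(ens, backgrounds, pat, "c1", "c2")
        e1 = pe.epe(ens, backgrounds, pat, "c1")
        e2 = pe.epe(ens, backgrounds, pat, "c2")
        assert d.depe == pytest.approx(
            float(np.mean(e1.log2_ratios - e2.log2_ratios)), abs=1e-12
        )

    def test_one_vs_rest_uses_mean_of_other_classes(self, backgrounds):
        ens = tiny_ensemble(seed=8, n_classes=3)
        pat = Pattern("p", "TGACTCAG")
        r = pe.depe_one_vs_rest(ens, backgrounds, pat, "c1")
        base, ins = pe._predict_pairs(ens, backgrounds, pat, None)
        expected = np.log2(ins[:, 0] / base[:, 0]) - (
            np.log2(ins[:, 1:].mean(axis=1) / base[:, 1:].mean(axis=1))
        )
        assert r.depe == pytest.approx(float(expected.mean()))


class TestGIA:
    def test_constant_model_gives_zero(self, backgrounds):
        assert pe.gia_effect(
            constant_ensemble(), backgrounds, Pattern("p", "ACGTACGT"), "c1"
        ) == 0.0

    def test_identity_pattern_gives_zero(self, backgrounds):
        ens = tiny_ensemble(seed=9)
        seq = backgrounds.sequences[0]
        center = (len(seq) - 8) // 2
        pair = pe.BackgroundSet([seq, seq], source="synthetic")
        assert pe.gia_effect(ens, pair, Pattern("p", seq[center:center + 8]), "c1") == 0.0


class TestMotifScreen:
    @pytest.fixture()
    def panel(self):
        return [pwm_from_consensus(f"m{i}", c) for i, c in enumerate(
            ["TGACTCAG", "CACGTGAC", "GGGCGGGG", "TTTATAAA"]
        )]

    def test_bonferroni_uses_pattern_count(self, backgrounds, panel):
        tab = pe.motif_screen(tiny_ensemble(seed=1), backgrounds, panel, classes=["c1"])
        assert np.allclose(
            tab["p_adjusted"], np.minimum(1.0, tab["p_value"] * len(panel))
        )

    def test_order_invariance(self, backgrounds, panel):
        ens = tiny_ensemble(seed=2)
        a = pe.motif_screen(ens, backgrounds, panel, classes=["c1"])
        b = pe.motif_screen(ens, backgrounds, panel[::-1], classes=["c1"])
        merged = a.merge(b, on="pattern_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["effect_a"], merged["effect_b"])
        assert np.allclose(merged["p_adjusted_a"], merged["p_adjusted_b"])

    def test_bh_is_monotone_and_no_larger_than_bonferroni_times_rank(self, rng):
        p = rng.uniform(size=12)
        bh = pe._adjust(p, "bh", 12)
        assert np.all(bh >= p) and np.all(bh <= 1)
        # BH never exceeds Bonferroni
        assert np.all(bh <= pe._adjust(p, "bonferroni", 12) + 1e-12)

    def test_rows_per_class_and_pair(self, backgrounds, panel):
        ens = tiny_ensemble(seed=3)
        tab = pe.motif_screen(
            ens, backgrounds, panel, classes=["c1", "c2"],
            class_pairs=[("c1", "c2")],
        )
        assert len(tab) == 3 * len(panel)
        assert set(tab["kind"]) == {"epe", "depe"}

    def test_one_vs_rest_mode(self, backgrounds, panel):
        ens = tiny_ensemble(seed=4, n_classes=3)
        tab = pe.motif_screen(ens, backgrounds, panel, one_vs_rest=True)
        assert len(tab) == 3 * len(panel)
        assert set(tab["class2"]) == {"rest"}

    def test_empty_panel_rejected(self, backgrounds):
        with pytest.raises(ValueError, match="non-empty"):
            pe.motif_screen(tiny_ensemble(), backgrounds, [], classes=["c1"])


class TestSpacingScan:
    def test_one_row_per_spacing_sorted(self, backgrounds):
        ens = tiny_ensemble(seed=5)
        a, b = Pattern("a", "TTGT"), Pattern("b", "ATGCAA")
        tab = pe.spacing_scan(ens, backgrounds, a, b, list(range(11)), "c1")
        assert list(tab["spacing"]) == list(range(11))

    def test_oversized_spacing_skipped_with_warning(self, backgrounds):
        ens = tiny_ensemble(seed=6)
        a, b = Pattern("a", "TTGT"), Pattern("b", "ATGCAA")
        with pytest.warns(UserWarning, match="skipped"):
            tab = pe.spacing_scan(ens, backgrounds, a, b, [0, 25], "c1")
        assert list(tab["spacing"]) == [0]

    def test_both_orders_flag_doubles_rows(self, backgrounds):
        ens = tiny_ensemble(seed=7)
        a, b = Pattern("a", "TTGT"), Pattern("b", "ATGCAA")
        tab = pe.spacing_scan(ens, backgrounds, a, b, [0, 1], "c1", both_orders=True)
        assert len(tab) == 4 and set(tab["order"]) == {"ab", "ba"}


class TestDifferentialSaliency:
    def test_identical_heads_give_zero_vector(self, rng):
        ens = identical_head_ensemble()
        seq = "".join(rng.choice(list("ACGT"), 30))
        assert np.allclose(pe.differential_saliency(ens, seq, "c1", "c2"), 0.0)

    def test_length_matches_input(self, rng):
        ens = tiny_ensemble(seed=8)
        seq = "".join(rng.choice(list("ACGT"), 30))
        assert pe.differential_saliency(ens, seq, "c1", "c2").shape == (30,)

    def test_antisymmetric_in_class_order(self, rng):
        ens = tiny_ensemble(seed=9)
        seq = "".join(rng.choice(list("ACGT"), 30))
        s12 = pe.differential_saliency(ens, seq, "c1", "c2")
        s21 = pe.differential_saliency(ens, seq, "c2", "c1")
        assert np.allclose(s12, -s21)


class TestSampleBackgrounds:
    def _dataset(self, labels):
        labels = np.asarray(labels)
        seqs = ["ACGTACGTAC"] * len(labels)
        return LabeledDataset(
            seqs, labels, [f"c{i}" for i in range(labels.shape[1])], window_length=10
        )

    def test_closed_random_excludes_any_positive(self):
        labels = np.array([[0, 0]] * 5 + [[1, 0], [0, 1], [1, 1]])
        ds = self._dataset(labels)
        bg = pe.sample_backgrounds(ds, "closed_random", M=5, seed=1)
        assert len(bg) == 5 and bg.source == "closed_random"

    def test_reproducible_for_fixed_seed(self):
        ds = self._dataset(np.zeros((40, 2), dtype=int))
        a = pe.sample_backgrounds(ds, "closed_random", M=10, seed=7)
        b = pe.sample_backgrounds(ds, "closed_random", M=10, seed=7)
        assert a.sequences == b.sequences

    def test_insufficient_pool_errors(self):
        ds = self._dataset(np.ones((5, 1), dtype=int))
        with pytest.raises(ValueError, match="eligible"):
            pe.sample_backgrounds(ds, "closed_random", M=3, seed=0)

    def test_promoter_selection_requires_mask(self):
        ds = self._dataset(np.zeros((10, 1), dtype=int))
        with pytest.raises(ValueError, match="mask"):
            pe.sample_backgrounds(ds, "promoter_closed", M=2, seed=0)


class TestBackgroundSet:
    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            pe.BackgroundSet(["ACGT"], source="user")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pe.BackgroundSet(["ACGT", "ACG"], source="user")

    def test_packaged_default_set(self):
        bg = pe.default_backgrounds()
        assert len(bg) == 24 and bg.window_length == 100 and bg.source == "synthetic"

    def test_fasta_round_trip(self, tmp_path, backgrounds):
        backgrounds.to_fasta(tmp_path / "bg.fa")
        back = pe.BackgroundSet.from_fasta(tmp_path / "bg.fa")
        assert back.sequences == backgrounds.sequences


def test_results_to_tsv_handles_both_kinds(tmp_path, backgrounds):
    ens = tiny_ensemble(seed=10)
    pat = Pattern("p", "TGACTCAG")
    results = [
        pe.epe(ens, backgrounds, pat, "c1"),
        pe.depe(ens, backgrounds, pat, "c1", "c2"),
    ]
    out = tmp_path / "out.tsv"
    pe.results_to_tsv(results, out)
    tab = pd.read_csv(out, sep="\t")
    assert list(tab.columns) == [
        "pattern_id", "class", "effect", "W", "p_value", "p_adjusted", "M",
        "n_zero_dropped",
    ]
    assert len(tab) == 2
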