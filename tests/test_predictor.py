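import numpy as np
import pandas as pd
import pytest

from groovescan.designs import AA_ORDER
from groovescan.predictor import (TrainConfig, calibrate, load_ensemble,
                                  make_training_set, make_training_set_ms,
                                  percent_rank, predict, predict_many,
                                  save_ensemble, train_ensemble)
from groovescan.workflows import planted_motif_peptides, rank_auc

TINY = TrainConfig(hidden=(8,), encodings=("sparse",), n_partitions=2,
                   n_seeds=1, max_epochs=250, patience=30)


def _toy_table(design, n=60, rounds=3, seed=0):
    """Peptide table where W at the first randomized position decides selection."""
    rng = np.random.default_rng(seed)
    rows = []
    seen = set()
    while len(rows) < n:
        core = "".join(rng.choice(list(AA_ORDER.replace("W", "")), 9))
        if core in seen:
            continue
        seen.add(core)
        binder = rng.random() < 0.5
        if binder:
            core = "W" + core[1:]
        pep = design.flank5_aa + core + design.flank3_aa
        fr = rounds if binder else 0
        row = {"peptide": pep}
        for r in range(rounds + 1):
            row[f"reads_r{r}"] = 1 if (r == 0 or binder) else 0
        row["final_round"] = fr
        rows.append(row)
    return pd.DataFrame(rows)


class TestMakeTrainingSet:
    def test_linear_target_map(self, design9):
        df = pd.DataFrame([
            {"peptide": "AA" + "A" * 9 + "WEEG", "reads_r0": 1, "reads_r1": 0,
             "reads_r2": 0, "reads_r3": 0, "reads_r4": 0, "reads_r5": 1,
             "final_round": 5},
            {"peptide": "AA" + "C" * 9 + "WEEG", "reads_r0": 1, "reads_r1": 0,
             "reads_r2": 1, "reads_r3": 0, "reads_r4": 0, "reads_r5": 0,
             "final_round": 2},
            {"peptide": "AA" + "D" * 9 + "WEEG", "reads_r0": 1, "reads_r1": 0,
             "reads_r2": 0, "reads_r3": 0, "reads_r4": 0, "reads_r5": 0,
             "final_round": 0},
        ])
        ex = {e.peptide: e for e in make_training_set(df, design9)}
        assert ex["A" * 9].target == 1.0           # round 5 of 5
        assert ex["C" * 9].target == pytest.approx(0.4)  # round 2 of 5
        assert ex["D" * 9].target == 0.0
        assert ex["D" * 9].origin == "naive_only"
        # only the randomized residues are emitted
        assert all(len(p) == 9 for p in ex)

    def test_cap_preserves_round_proportions(self, design9):
        table = _toy_table(design9, n=400, rounds=2, seed=1)
        ex = make_training_set(table, design9, cap=100, seed=2)
        assert len(ex) <= 105
        frac_pos = np.mean([e.target > 0 for e in ex])
        true_frac = (table["final_round"] > 0).mean()
        assert abs(frac_pos - true_frac) < 0.1

    def test_no_negatives_rejected(self, design9):
        table = _toy_table(design9, n=50, rounds=2, seed=3)
        table = table[table["final_round"] > 0]
        with pytest.raises(ValueError, match="no negative examples"):
            make_training_set(table, design9)


class TestMakeTrainingSetMS:
    def test_pairing_and_composition(self):
        pos = ["ACDEFGHIKL", "MNPQRSTVWY"]
        ex = make_training_set_ms(pos, seed=1)
        assert len(ex) == 4  # 1:1 pairing
        for p, s in zip(ex[::2], ex[1::2]):
            assert p.target == 1.0 and s.target == 0.0
            assert sorted(p.peptide) == sorted(s.peptide)
            assert p.peptide != s.peptide

    def test_seeded_determinism(self):
        pos = ["ACDEFGHIKL", "MNPQRSTVWY", "AAWDPDKTVY"]
        a = make_training_set_ms(pos, seed=5)
        b = make_training_set_ms(pos, seed=5)
        assert [e.peptide for e in a] == [e.peptide for e in b]

    def test_length_one_rejected(self):
        with pytest.raises(ValueError, match="scramble"):
            make_training_set_ms(["A"], seed=0)


class TestTrainEnsemble:
    def test_separable_toy_data(self, design9):
        table = _toy_table(design9, n=120, rounds=3, seed=4)
        ex = make_training_set(table, design9, seed=5)
        ens = train_ensemble(ex, TINY, seed=6)
        peps = [e.peptide for e in ex]
        scores = predict_many(ens, peps)
        s = dict(zip(scores["peptide"], scores["score"]))
        pos = np.array([s[e.peptide] for e in ex if e.target > 0])
        neg = np.array([s[e.peptide] for e in ex if e.target == 0])
        assert rank_auc(pos, neg) == 1.0
        assert scores["score"].between(0, 1).all()

    def test_bit_reproducible(self, design9):
        table = _toy_table(design9, n=60, rounds=3, seed=7)
        ex = make_training_set(table, design9, seed=8)
        a = train_ensemble(ex, TINY, seed=9)
        b = train_ensemble(ex, TINY, seed=9)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.W1, mb.W1)
            assert np.array_equal(ma.w2, mb.w2)
            assert ma.b2 == mb.b2

    def test_needs_both_classes(self):
        from groovescan.predictor import TrainingExample
        ex = [TrainingExample("ACDEFGHIK", 1.0, "ms_positive")] * 10
        with pytest.raises(ValueError, match="positive and zero"):
            train_ensemble(ex, TINY)

    @staticmethod
    def _shifted_core_peptides(n, seed):
        """13mers with a 9mer anchor motif planted at a per-peptide offset.

        Offsets span the full feasible range (0..4) so the alignment the
        network learns is pinned: a globally shifted consensus would misfit
        the boundary-offset peptides.
        """
        from groovescan.designs import AA_INDEX
        from groovescan.enrichment import uniprot_background
        core_anchors = {0: "W", 3: "DE", 8: "ST"}
        bg = uniprot_background().to_numpy()
        r = np.random.default_rng(seed)
        peps, offs, seen = [], [], set()
        while len(peps) < n:
            off = int(r.integers(0, 5))
            draw = r.choice(20, size=13, p=bg)
            for rel, res in core_anchors.items():
                choices = [AA_INDEX[a] for a in res]
                draw[off + rel] = choices[r.integers(len(choices))]
            p = "".join(AA_ORDER[i] for i in draw)
            if p in seen:
                continue
            seen.add(p)
            peps.append(p)
            offs.append(off)
        return peps, offs

    def test_register_scanning_recovers_shifted_core(self):
        pos, _ = self._shifted_core_peptides(300, seed=21)
        # scrambled negatives force the network to learn positional anchors
        ex = make_training_set_ms(pos, seed=11)
        cfg = TrainConfig(hidden=(8,), encodings=("sparse",), n_partitions=2,
                          n_seeds=1, max_epochs=250, patience=30, rescan_every=3)
        ens = train_ensemble(ex, cfg, seed=13)
        test_pos, test_offs = self._shifted_core_peptides(100, seed=22)
        out = predict_many(ens, test_pos)
        match = out["core_offset"].to_numpy() == np.array(test_offs)
        assert match.mean() >= 0.8


class TestPredict:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained(design9):
        table = _toy_table(design9, n=120, rounds=3, seed=20)
        ex = make_training_set(table, design9, seed=21)
        return train_ensemble(ex, TINY, seed=22)

    def test_9mer_offset_zero(self, trained):
        _s, off = predict(trained, "ACDEFGHIK")
        assert off == 0

    def test_invert_option(self, trained):
        s, _ = predict(trained, "WCDEFGHIK")
        si, _ = predict(trained, "WCDEFGHIK", invert=True)
        assert si == pytest.approx(1.0 - s)

    def test_too_short(self, trained):
        with pytest.raises(ValueError, match="too short"):
            predict(trained, "ACDEFGHI")

    def test_consensus_beats_scramble(self, trained):
        s_w, _ = predict(trained, "WAAAAAAAA")
        s_scr, _ = predict(trained, "AAAAWAAAA")  # W away from P1
        assert s_w > s_scr


class TestPercentRank:
    @pytest.fixture(scope="class")
    @staticmethod
    def calibrated(design9):
        table = _toy_table(design9, n=120, rounds=3, seed=30)
        ex = make_training_set(table, design9, seed=31)
        ens = train_ensemble(ex, TINY, seed=32)
        return calibrate(ens, n=2000, length=9, seed=33)

    def test_extremes_and_median(self, calibrated):
        cal = calibrated.rank_calibration
        assert percent_rank(calibrated, cal.max() + 1) == 0.0
        med = float(np.median(cal))
        assert abs(percent_rank(calibrated, med) - 50.0) < 1.0

    def test_monotone_nonincreasing(self, calibrated):
        sweep = np.linspace(0, 1, 101)
        ranks = [percent_rank(calibrated, s) for s in sweep]
        assert all(b <= a for a, b in zip(ranks, ranks[1:]))

    def test_uncalibrated_rejected(self, design9):
        table = _toy_table(design9, n=60, rounds=3, seed=34)
        ex = make_training_set(table, design9, seed=35)
        ens = train_ensemble(ex, TINY, seed=36)
        with pytest.raises(ValueError, match="uncalibrated"):
            percent_rank(ens, 0.5)

    def test_save_load_roundtrip(self, calibrated, tmp_path):
        p = tmp_path / "model.json"
        save_ensemble(calibrated, p)
        loaded = load_ensemble(p)
        pep = "WCDEFGHIK"
        assert predict(loaded, pep) == predict(calibrated, pep)
        assert percent_rank(loaded, 0.7) == percent_rank(calibrated, 0.7)
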