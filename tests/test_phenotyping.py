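"""Normalization arithmetic, test statistics, and phenotype-call recovery."""

import numpy as np
import pandas as pd
import pytest

from txlogic.phenotyping import (
    NormalizedBUO,
    build_response_matrix,
    classify_phenotype,
    cohens_d,
    normalize_plate,
    standardize_to_max,
    welch_two_tailed,
)
from txlogic.synthetic_data import (
    IPTG,
    NoiseModel,
    Phenotype,
    SimPlate,
    TFSpec,
    profile_from_phenotype,
    simulate_buo_plate,
)


def make_plate(rows):
    cols = ["plate_id", "well", "sample_type", "tf_id", "operator", "position",
            "ligands", "replicate", "od600", "fluorescence"]
    return SimPlate(wells=pd.DataFrame(rows, columns=cols), seed=0)


def buo(no, with_, **kw):
    defaults = dict(tf_id="t", operator="O1", position="proximal", reference=1.0)
    defaults.update(kw)
    return NormalizedBUO(s_no_ligand=np.asarray(no, float),
                         s_with_ligand=np.asarray(with_, float), **defaults)


class TestNormalizePlate:
    def test_hand_computed_three_well_example(self):
        # blanks average to OD 0.05 / fluor 100; wells then normalize as
        # (F - 100) / (OD - 0.05), negatives clipped
        rows = [
            ("p", "A1", "blank", "", "", "", "", 0, 0.04, 90.0),
            ("p", "A2", "blank", "", "", "", "", 1, 0.06, 110.0),
            ("p", "B1", "tf", "t", "O1", "proximal", "", 0, 0.55, 40100.0),
            ("p", "B2", "tf", "t", "O1", "proximal", "", 1, 0.30, 10100.0),
            ("p", "B3", "tf", "t", "O1", "proximal", "", 2, 0.25, 60.0),
        ]
        norm, excluded = normalize_plate(make_plate(rows))
        assert norm.normalized.tolist() == pytest.approx(
            [40000.0 / 0.5, 10000.0 / 0.25, 0.0])
        assert excluded.empty

    def test_well_at_blank_od_excluded(self):
        rows = [
            ("p", "A1", "blank", "", "", "", "", 0, 0.05, 100.0),
            ("p", "B1", "tf", "t", "O1", "proximal", "", 0, 0.05, 500.0),
            ("p", "B2", "tf", "t", "O1", "proximal", "", 1, 0.50, 500.0),
        ]
        norm, excluded = normalize_plate(make_plate(rows))
        assert excluded.well.tolist() == ["B1"]
        assert norm.well.tolist() == ["B2"]

    def test_requires_blank_wells(self):
        rows = [("p", "B1", "tf", "t", "O1", "proximal", "", 0, 0.5, 500.0)]
        with pytest.raises(ValueError, match="blank"):
            normalize_plate(make_plate(rows))


class TestStandardizeToMax:
    def stratum_rows(self, operator, lac_null_fluor, tf_fluor):
        rows = [("p", f"bl{operator}{i}", "blank", "", "", "", "", i, 0.05, 100.0)
                for i in range(2)]
        for i in range(2):
            rows.append(("p", f"ln{operator}{i}", "lac_null", "lac_null",
                         operator, "proximal", "", i, 0.55, lac_null_fluor))
            rows.append(("p", f"tf{operator}{i}", "tf", "t", operator,
                         "proximal", "", i, 0.55, tf_fluor))
            rows.append(("p", f"tg{operator}{i}", "tf", "t", operator,
                         "proximal", IPTG, i, 0.55, tf_fluor))
        return rows

    def test_lac_null_wells_average_to_one(self):
        norm, _ = normalize_plate(make_plate(self.stratum_rows("O1", 50100.0, 25100.0)))
        _, df = standardize_to_max(norm)
        ln = df[df.sample_type == "lac_null"]
        assert ln.standardized.mean() == pytest.approx(1.0)

    def test_strata_standardize_independently(self):
        rows = (self.stratum_rows("O1", 50100.0, 25100.0)
                + self.stratum_rows("Ottg", 20100.0, 10100.0))
        norm, _ = normalize_plate(make_plate(rows))
        buos, _ = standardize_to_max(norm)
        # different raw maxima, identical standardized fractions
        for b in buos:
            assert b.s_no_ligand.mean() == pytest.approx(0.5)

    def test_missing_stratum_control_rejected_by_name(self):
        rows = self.stratum_rows("O1", 50100.0, 25100.0)
        rows = [r for r in rows if r[2] != "lac_null"]
        norm, _ = normalize_plate(make_plate(rows))
        with pytest.raises(ValueError, match="O1"):
            standardize_to_max(norm)


class TestWelch:
    def test_identical_vectors_give_p_one(self):
        assert welch_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_large_shift_tiny_variance_significant(self):
        a = [1.0, 2.0, 3.0]
        b = [1001.0, 1002.0, 1003.0]
        assert welch_two_tailed(a, b) < 1e-3

    def test_zero_variance_separated_gives_p_zero(self):
        assert welch_two_tailed([1.0, 1.0], [2.0, 2.0]) == 0.0

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            welch_two_tailed([1.0], [1.0, 2.0])

    def test_agrees_with_permutation_oracle(self):
        # significance decisions at alpha 0.001 match an independent
        # permutation test on 50 random small fixtures; n >= 8 per group so
        # the permutation distribution can resolve p below alpha at all
        rng = np.random.default_rng(1234)
        alpha = 1e-3
        n_perm = 20_000
        for i in range(50):
            n = int(rng.integers(8, 13))
            a = rng.normal(0.0, 1.0, n)
            shift = 0.0 if i % 2 == 0 else 8.0
            b = rng.normal(shift, 1.5, n)
            p_welch = welch_two_tailed(a, b)
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
            perm = pooled[idx]
            diffs = np.abs(perm[:, :n].mean(axis=1) - perm[:, n:].mean(axis=1))
            p_perm = (np.sum(diffs >= obs) + 1) / (n_perm + 1)
            assert (p_welch < alpha) == (p_perm < alpha), (i, p_welch, p_perm)


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_definition(self):
        # means 0 and 1, pooled SD 1 -> d = 1
        a = np.array([-1.0, 0.0, 1.0])
        b = a + 1.0
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_hand_calculation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 5.0, 7.0, 9.0])
        pooled = np.sqrt(((3 * a.var(ddof=1)) + (3 * b.var(ddof=1))) / 6)
        assert cohens_d(a, b) == pytest.approx(abs(a.mean() - b.mean()) / pooled)

    def test_zero_sd_sentinel(self):
        assert cohens_d([1.0, 1.0], [2.0, 2.0]) == np.inf


class TestClassifyPhenotype:
    def test_anti_repressor_called_significant(self):
        rng = np.random.default_rng(0)
        b = buo(0.9 * rng.lognormal(0, 0.05, 6), 0.09 * rng.lognormal(0, 0.05, 6))
        call = classify_phenotype(b)
        assert call.phenotype is Phenotype.X_ANTI
        assert call.p_value < 1e-3 and call.significant

    @pytest.mark.parametrize(
        "levels, expected",
        [((0.95, 0.95), Phenotype.X_NULL), ((0.03, 0.03), Phenotype.X_SUPER)],
    )
    def test_fifty_percent_rule(self, levels, expected):
        rng = np.random.default_rng(3)
        b = buo(levels[0] * rng.lognormal(0, 0.05, 6),
                levels[1] * rng.lognormal(0, 0.05, 6))
        assert classify_phenotype(b).phenotype is expected

    def test_exact_half_tie_called_null(self):
        b = buo([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert classify_phenotype(b).phenotype is Phenotype.X_NULL

    def test_recovery_over_seeded_plates(self, default_noise):
        # >= 99% of calls over 100 plates x 4 phenotypes match the
        # generating phenotype at default noise (full 500-seed version in
        # the acceptance suite)
        tfs = {p: TFSpec(f"t_{p.value}", IPTG, "HQN", p) for p in Phenotype}
        profiles = [profile_from_phenotype(t, "Ottg", "proximal")
                    for t in tfs.values()]
        wrong = total = 0
        for seed in range(100):
            plate = simulate_buo_plate(profiles, default_noise, seed=seed)
            buos, _ = standardize_to_max(normalize_plate(plate)[0])
            for b in buos:
                expected = Phenotype(b.tf_id.removeprefix("t_"))
                total += 1
                wrong += classify_phenotype(b).phenotype is not expected
        assert wrong / total <= 0.01

    def test_correct_calls_stable_as_cv_decreases(self):
        # a call that is correct at high noise stays correct as cv shrinks
        tf = TFSpec("a", IPTG, "HQN", Phenotype.X_ANTI)
        prof = profile_from_phenotype(tf, "Ottg", "proximal")
        for cv in (0.10, 0.05, 0.02, 0.0):
            noise = NoiseModel(cv_fluorescence=cv, cv_od=cv)
            plate = simulate_buo_plate([prof], noise, seed=99)
            buos, _ = standardize_to_max(normalize_plate(plate)[0])
            assert classify_phenotype(buos[0]).phenotype is Phenotype.X_ANTI


class TestResponseMatrix:
    COGNATE = {"YQR": {"O1"}, "HQN": {"Ottg"}, "KSL": {"Oagg"}}

    def call(self, phen, significant):
        return classify_phenotype(
            buo(np.array([0.9, 0.91, 0.9]), np.array([0.09, 0.1, 0.09]))
        ) if significant and phen is Phenotype.X_ANTI else _fixed_call(phen, significant)

    def grid(self, inject_noncognate_anti=False):
        calls = {}
        for d in self.COGNATE:
            for o in ("O1", "Ottg", "Oagg"):
                cognate = o in self.COGNATE[d]
                phen = Phenotype.X_ANTI if cognate else Phenotype.X_NULL
                calls[(d, o)] = _fixed_call(phen, significant=cognate)
        if inject_noncognate_anti:
            calls[("YQR", "Oagg")] = _fixed_call(Phenotype.X_ANTI, True)
        return calls

    def test_all_diagonal_anti_counts_grid_dimension(self):
        m = build_response_matrix(self.grid(), self.COGNATE)
        assert m.cognate_anti_count == 3
        assert m.noncognate_significant_count == 0

    def test_injected_off_diagonal_counts_as_crosstalk(self):
        m = build_response_matrix(self.grid(inject_noncognate_anti=True),
                                  self.COGNATE)
        assert m.noncognate_significant_count == 1

    def test_incomplete_grid_rejected_with_missing_cells(self):
        calls = self.grid()
        del calls[("YQR", "Ottg")]
        with pytest.raises(ValueError, match="missing"):
            build_response_matrix(calls, self.COGNATE)

    def test_frame_layout(self):
        frame = build_response_matrix(self.grid(), self.COGNATE).to_frame()
        assert frame.loc["HQN", "Ottg"] == "X_anti"
        assert frame.shape == (3, 3)


def _fixed_call(phen, significant):
    from txlogic.phenotyping import PhenotypeCall

    return PhenotypeCall(phenotype=phen, p_value=1e-6 if significant else 0.5,
                         cohen_d=5.0 if significant else 0.1,
                         mean_levels=(0.9, 0.1) if significant else (0.9, 0.9),
                         significant=significant)
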