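"""Region labels, background statistics, significance and rank tests."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import linkerdock as ld
from linkerdock.sitestats import (
    BackgroundStats,
    assign_region,
    compute_background,
    flag_significant,
    mann_whitney,
    normality_test,
)
from linkerdock.structures import Atom, Complex, Ligand, RegionAnnotation


@pytest.fixture(scope="module")
def annotated_complex():
    models, annotations = ld.make_toy_protein(ld.ToyProteinSpec(n_snapshots=1, seed=31))
    return Complex(protein=models[0]), annotations


def _probe_at(xyz, lid="p"):
    return Ligand(ligand_id=lid, species="probe",
                  atoms=[Atom(serial=1, name="O1", element="O", coords=xyz,
                              interaction_class="donor_acceptor")])


class TestAssignRegion:
    def test_far_ligand_is_nonspecific(self, annotated_complex):
        complex_, annotations = annotated_complex
        far = complex_.protein.coords().mean(axis=0) + np.array([200.0, 0.0, 0.0])
        label = assign_region(_probe_at(far), complex_, annotations)
        assert label.category == "nonspecific"
        assert label.regions_touched == frozenset()

    def test_linker_contact_only(self, annotated_complex):
        complex_, annotations = annotated_complex
        linker = next(a for a in annotations if a.region_name == "linker")
        seq = sorted(s for _, s in linker.members)[len(linker.members) // 2]
        res = complex_.protein.residue_index()[("A", seq, "")]
        near = res.atom("OG").coords + np.array([0.0, 0.0, 2.9])
        label = assign_region(_probe_at(near), complex_, annotations)
        assert label.regions_touched == frozenset({"linker"})
        assert label.category == "linker"

    def test_bridging_between_linker_and_pocket(self):
        # hand-built model: one linker residue and one pocket residue close
        # enough that a single ligand touches both
        res_l = ld.Residue(chain_id="A", seq_number=1, name="SER", atoms=[
            Atom(serial=1, name="OG", element="O", coords=(0.0, 0.0, 0.0),
                 interaction_class="donor_acceptor")])
        res_p = ld.Residue(chain_id="A", seq_number=2, name="SER", atoms=[
            Atom(serial=2, name="OG", element="O", coords=(6.0, 0.0, 0.0),
                 interaction_class="donor_acceptor")])
        protein = ld.ProteinModel(model_id="b", chains={"A": [res_l, res_p]})
        annotations = [
            RegionAnnotation("linker", frozenset({("A", 1)})),
            RegionAnnotation("pocket", frozenset({("A", 2)})),
        ]
        bridging = assign_region(_probe_at((3.0, 0.0, 0.0)), Complex(protein=protein),
                                 annotations)
        assert bridging.category == "bridging"
        assert bridging.regions_touched == {"linker", "pocket"}
        pocket_only = assign_region(_probe_at((7.0, 0.0, 0.0)), Complex(protein=protein),
                                    annotations)
        assert pocket_only.category == "pocket"

    def test_unknown_region_residues_error(self, annotated_complex):
        complex_, _ = annotated_complex
        bad = [RegionAnnotation("linker", frozenset({("Z", 999)}))]
        with pytest.raises(ValueError):
            assign_region(_probe_at((0, 0, 0)), complex_, bad)


class TestBackground:
    def test_two_record_closed_form(self):
        records = pd.DataFrame({"delta_g": [-4.0, -5.0],
                                "category": ["nonspecific", "nonspecific"]})
        bg = compute_background(records)
        assert bg.mean == pytest.approx(-4.5)
        assert bg.sd == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert bg.n == 2

    def test_specific_categories_excluded(self):
        records = pd.DataFrame({
            "delta_g": [-4.0, -5.0, -9.0, -9.0, -9.0],
            "category": ["nonspecific", "other", "linker", "pocket", "bridging"],
        })
        bg = compute_background(records)
        assert bg.n == 2 and bg.mean == pytest.approx(-4.5)

    def test_too_few_records_error(self):
        records = pd.DataFrame({"delta_g": [-4.0], "category": ["nonspecific"]})
        with pytest.raises(ValueError):
            compute_background(records)

    def test_parameter_recovery_from_synthetic_table(self):
        table = ld.make_dg_table(ld.DgTableSpec(background_mean=-4.5, background_sd=0.25,
                                                n_background=10_000, seed=13))
        bg = compute_background(table)
        assert bg.mean == pytest.approx(-4.5, abs=0.01)
        assert bg.sd == pytest.approx(0.25, abs=0.01)


class TestFlagSignificant:
    def test_boundary_inclusive(self):
        bg = BackgroundStats(mean=-4.0, sd=0.2, n=20)
        assert flag_significant(-4.0 - 3 * 0.2, bg)
        assert not flag_significant(-4.0 - 3 * 0.2 + 1e-9, bg)

    def test_published_style_background_arithmetic(self):
        # a background of −4.46 ± 0.25 kcal/mol puts the 3-SD cutoff at −5.21
        bg = BackgroundStats(mean=-4.46, sd=0.25, n=20)
        assert flag_significant(-5.30, bg)
        assert not flag_significant(-5.10, bg)

    def test_monotone_in_affinity(self):
        bg = BackgroundStats(mean=-4.5, sd=0.3, n=30)
        rng = np.random.default_rng(0)
        values = sorted(rng.uniform(-7.0, -3.0, 50))
        flags = [flag_significant(v, bg) for v in values]
        # once a (more negative) value is flagged, everything stronger is too
        assert flags == sorted(flags, reverse=True)

    def test_degenerate_sd(self):
        bg = BackgroundStats(mean=-4.5, sd=0.0, n=5)
        assert flag_significant(-4.6, bg)
        assert not flag_significant(-4.5, bg)


class TestOccupancy:
    def _runs_with_counts(self, counts):
        runs = []
        for m, c in enumerate(counts):
            rounds = []
            for k in range(10):
                cat = "linker" if k < c else "nonspecific"
                rec = ld.RoundRecord(round_index=k + 1, ligand_species="s", pose=None,
                                     delta_g=-4.0)
                rec.region_label = ld.RegionLabel(category=cat, regions_touched=frozenset())
                rounds.append(rec)
            runs.append(ld.SequentialRun(model_id=f"m{m}", time_label_ns=10.0 * (m + 1),
                                         ligand_species="s", rounds=rounds,
                                         final_complex=None))
        return runs

    def test_full_occupancy(self):
        occ = ld.occupancy_summary(self._runs_with_counts([10, 10]), "linker")
        assert occ.mean_count == 10.0 and occ.sd_count == 0.0

    def test_two_model_closed_form(self):
        occ = ld.occupancy_summary(self._runs_with_counts([4, 6]), "linker")
        assert occ.mean_count == pytest.approx(5.0)
        assert occ.sd_count == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert occ.n_models == 2

    def test_bridging_counts_toward_linker(self):
        runs = self._runs_with_counts([3])
        runs[0].rounds[5].region_label = ld.RegionLabel(category="bridging",
                                                        regions_touched=frozenset())
        occ = ld.occupancy_summary(runs, "linker")
        assert occ.mean_count == 4.0


class TestMannWhitney:
    def test_textbook_separated_groups(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
        assert res.p_value >= 0.99

    @pytest.mark.parametrize("n1, n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(1, 7)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        pooled = np.round(rng.normal(size=n1 + n2), 1)  # rounding provokes ties
        a, b = pooled[:n1], pooled[n1:]
        res = mann_whitney(a, b, mode="exact")
        # independent oracle: direct pair counting for every labeling
        def u_of(group_x, group_y):
            u = 0.0
            for x in group_x:
                for y in group_y:
                    u += 1.0 if x > y else (0.5 if x == y else 0.0)
            return u
        mu = n1 * n2 / 2.0
        obs = abs(u_of(a, b) - mu)
        hits = sum(
            1 for idx in combinations(range(n1 + n2), n1)
            if abs(u_of(pooled[list(idx)],
                        pooled[[i for i in range(n1 + n2) if i not in idx]]) - mu)
            >= obs - 1e-12
        )
        assert res.p_value == pytest.approx(hits / comb(n1 + n2, n1), abs=1e-12)
        assert res.statistic == min(u_of(a, b), u_of(b, a))

    def test_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.8, 1.0, 25)
        res = mann_whitney(a, b, mode="normal_approx")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
        with pytest.raises(ValueError):
            mann_whitney(list(range(7)), list(range(7)), mode="exact")


class TestNormality:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(1).normal(0, 1, 500)
        assert normality_test(x).p_value > 0.01

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(2).exponential(1.0, 500)
        assert normality_test(x).p_value < 0.01

    def test_degenerate_and_small_samples_error(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])
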