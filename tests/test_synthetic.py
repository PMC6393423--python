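"""Ground-truth guarantees and determinism of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from tumormorph import BinaryMask, percent_necrosis
from tumormorph.synth import (
    Arm,
    CohortSpec,
    KiFieldSpec,
    PercolationSpec,
    SectionSpec,
    gen_cohort,
    gen_ki67_field,
    gen_percolation_mask,
    gen_section,
    percolation_dimension,
)
from tumormorph.zoning import boundary_distance

from conftest import make_disk


class TestPercolation:
    def test_p_one_retains_everything(self):
        mask = gen_percolation_mask(PercolationSpec(base=2, retain_prob=1.0, levels=3, seed=0))
        assert mask.shape == (8, 8) and mask.foreground_count == 64

    def test_subcritical_spec_rejected(self):
        with pytest.raises(ValueError, match="subcritical"):
            PercolationSpec(base=3, retain_prob=0.10, levels=2, seed=0)

    def test_oversized_raster_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            PercolationSpec(base=5, retain_prob=0.9, levels=7, seed=0)

    def test_determinism(self):
        spec = PercolationSpec(base=5, retain_prob=0.702, levels=4, seed=9)
        a, b = gen_percolation_mask(spec), gen_percolation_mask(spec)
        assert np.array_equal(a.grid, b.grid)

    def test_extinct_realization_returned_as_empty(self):
        # base 2, p 0.3 is supercritical (b^2 p = 1.2) but dies out often
        empties = sum(
            gen_percolation_mask(
                PercolationSpec(base=2, retain_prob=0.3, levels=4, seed=s)
            ).is_empty()
            for s in range(40)
        )
        assert empties > 0

    def test_pixel_count_scaling_matches_theory(self):
        """Over >= 100 non-extinct realizations at b=5, p=0.702, L=5 the mean
        of log5(pixel count)/L lies within 0.05 of log5(25 p) — the finest-
        scale slice of the theoretical scaling law."""
        b, p, levels = 5, 0.702, 5
        vals = []
        seed = 0
        while len(vals) < 100:
            seed += 1
            m = gen_percolation_mask(PercolationSpec(base=b, retain_prob=p, levels=levels, seed=seed))
            if m.is_empty():
                continue
            vals.append(np.log(m.foreground_count) / np.log(b) / levels)
        expected = np.log(b * b * p) / np.log(b)
        assert np.mean(vals) == pytest.approx(expected, abs=0.05)
        assert percolation_dimension(b, p) == pytest.approx(expected)


class TestSection:
    @pytest.mark.parametrize("pattern", ["compact_interior", "dispersed_peripheral"])
    @pytest.mark.parametrize("frac", [0.0, 0.075, 0.374])
    def test_truth_fraction_exact_and_inside_tumor(self, pattern, frac):
        img = gen_section(SectionSpec(radius_px=128, necrotic_fraction=frac,
                                      pattern=pattern, seed=5))
        assert not np.any(img.truth_necrosis.grid & ~img.tumor_mask.grid)
        if frac == 0.0:
            assert img.truth_necrosis.is_empty()
        else:
            realized = percent_necrosis(img.truth_necrosis, img.tumor_mask) / 100
            assert realized == pytest.approx(frac, abs=0.01)

    def test_target_fraction_example(self):
        img = gen_section(SectionSpec(radius_px=256, necrotic_fraction=0.374,
                                      pattern="compact_interior", seed=7))
        realized = percent_necrosis(img.truth_necrosis, img.tumor_mask) / 100
        assert 0.364 <= realized <= 0.384

    def test_compact_necrosis_lies_deeper_than_dispersed(self):
        means = {}
        for pattern in ("compact_interior", "dispersed_peripheral"):
            img = gen_section(SectionSpec(radius_px=256, necrotic_fraction=0.3,
                                          pattern=pattern, seed=5))
            d = boundary_distance(img.tumor_mask)
            means[pattern] = d[img.truth_necrosis.grid].mean()
        assert means["compact_interior"] > means["dispersed_peripheral"]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SectionSpec(radius_px=16, necrotic_fraction=0.1,
                        pattern="compact_interior", seed=0)
        with pytest.raises(ValueError):
            SectionSpec(radius_px=64, necrotic_fraction=1.2,
                        pattern="compact_interior", seed=0)
        with pytest.raises(ValueError):
            SectionSpec(radius_px=64, necrotic_fraction=0.1, pattern="ring", seed=0)

    def test_determinism(self):
        spec = SectionSpec(radius_px=64, necrotic_fraction=0.2,
                           pattern="dispersed_peripheral", seed=3)
        a, b = gen_section(spec), gen_section(spec)
        assert np.array_equal(a.rgb, b.rgb)
        assert a.truth_necrosis == b.truth_necrosis


class TestKi67Field:
    def test_extreme_fractions_give_uniform_labels(self):
        disk = make_disk(64)
        lo = gen_ki67_field(KiFieldSpec((0.0, 0.0, 0.0), 4.0, seed=1), disk)
        hi = gen_ki67_field(KiFieldSpec((1.0, 1.0, 1.0), 4.0, seed=1), disk)
        assert (lo.truth_nuclei["label"] == 0).all()
        assert (hi.truth_nuclei["label"] == 1).all()

    def test_realized_zone_fractions_within_three_binomial_se(self):
        disk = make_disk(256)
        field = gen_ki67_field(KiFieldSpec((0.45, 0.30, 0.15), 5.0, seed=3), disk)
        truth = field.truth_nuclei
        for zone, p in zip((1, 2, 3), (0.45, 0.30, 0.15)):
            sub = truth[truth["zone"] == zone]
            n = len(sub)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(sub["label"].mean() - p) <= 3 * se

    def test_labels_are_bernoulli_at_specified_rates_over_50_seeds(self):
        """Chi-square goodness of fit of per-zone positive counts against the
        generating rates, pooled over 50 fields, passes at alpha=0.001."""
        disk = make_disk(128)
        probs = (0.45, 0.30, 0.15)
        chi2, dof = 0.0, 0
        for seed in range(50):
            truth = gen_ki67_field(KiFieldSpec(probs, 5.0, seed=seed), disk).truth_nuclei
            for zone, p in zip((1, 2, 3), probs):
                n = int((truth["zone"] == zone).sum())
                if n == 0:
                    continue
                k = int(truth.loc[truth["zone"] == zone, "label"].sum())
                chi2 += (k - n * p) ** 2 / (n * p * (1 - p))
                dof += 1
        assert stats.chi2.sf(chi2, dof) > 0.001

    def test_nuclei_inside_tumor_and_non_overlapping(self):
        disk = make_disk(96)
        field = gen_ki67_field(KiFieldSpec((0.5, 0.5, 0.5), 5.0, seed=2), disk)
        t = field.truth_nuclei
        assert disk.grid[t["y"], t["x"]].all()
        xy = t[["x", "y"]].to_numpy(float)
        d2 = ((xy[:, None] - xy[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= (2 * 3.0 + 1.0) ** 2  # min center spacing

    def test_overcrowded_density_raises(self):
        from tumormorph.synth.ki67field import PlacementError

        disk = make_disk(48)
        with pytest.raises(PlacementError):
            gen_ki67_field(KiFieldSpec((0.5, 0.5, 0.5), 40.0, seed=0), disk)


class TestCohort:
    def test_determinism(self):
        spec = CohortSpec(arms=(Arm("a", 4, 300.0, 25.0),), seed=2)
        assert gen_cohort(spec).equals(gen_cohort(spec))

    def test_day0_group_mean_matches_start_mean(self):
        tab = gen_cohort(CohortSpec(arms=(Arm("a", 5, 400.0, 30.0),
                                          Arm("b", 7, 200.0, 20.0)), seed=4))
        from tumormorph import add_volumes

        d0 = add_volumes(tab).query("day == 0").groupby("group")["volume_mm3"].mean()
        assert np.allclose(d0, 106.9)

    def test_calipers_ordered_and_positive(self):
        tab = gen_cohort(CohortSpec(arms=(Arm("a", 6, 519.4, 62.9),), seed=11))
        assert (tab["length_mm"] >= tab["width_mm"]).all()
        assert (tab["width_mm"] > 0).all()

    def test_volume_round_trip_to_six_significant_figures(self):
        from tumormorph import add_volumes

        spec = CohortSpec(arms=(Arm("a", 4, 300.0, 25.0),), seed=8)
        df = add_volumes(gen_cohort(spec))
        v = df["length_mm"] * df["width_mm"] ** 2 / 2
        assert np.allclose(v, df["volume_mm3"], rtol=1e-6)

    def test_final_day_mean_near_target(self):
        tab = gen_cohort(CohortSpec(arms=(Arm("control", 6, 519.4, 62.9),),
                                    seed=11, days=(0, 22)))
        from tumormorph import add_volumes

        m = add_volumes(tab).query("day == 22")["volume_mm3"].mean()
        assert abs(m - 519.4) <= 3 * 62.9

    def test_larger_final_mean_gives_larger_expected_day22_mean(self):
        from tumormorph import add_volumes

        means = {"lo": [], "hi": []}
        for seed in range(30):
            tab = gen_cohort(CohortSpec(
                arms=(Arm("lo", 7, 202.6, 18.1), Arm("hi", 7, 519.4, 62.9)),
                seed=seed))
            d22 = add_volumes(tab).query("day == 22").groupby("group")["volume_mm3"].mean()
            means["lo"].append(d22["lo"])
            means["hi"].append(d22["hi"])
        assert np.mean(means["hi"]) > np.mean(means["lo"])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            Arm("a", 1, 100.0, 5.0)
        with pytest.raises(ValueError):
            Arm("a", 4, -1.0, 5.0)
        with pytest.raises(ValueError):
            CohortSpec(arms=(Arm("a", 4, 100.0, 5.0),), seed=0, days=(5, 2))
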