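import math

import numpy as np
import pytest

from shoxdel.region import DEL1, DEL2, WT, RegionModel, SampleSpec, build_region_model
from shoxdel.simulate import (
    simulate_cohort_ddpcr,
    simulate_ddpcr,
    simulate_depth,
    simulate_pool_snp_counts,
    simulate_population,
    target_copy_number,
)
from conftest import make_case


def segment_mean(track, interval):
    lo, hi = interval
    return track.depth[lo:hi].mean()


class TestSimulateDepth:
    def test_hom_del1_lacks_reads_inside_deletion(self, model):
        track = simulate_depth(model, make_case("c1", (DEL1, DEL1)), seed=1)
        lo, hi = model.del1
        assert np.all(track.depth[lo:hi] == 0)
        outside = np.concatenate([track.depth[:lo], track.depth[hi:]])
        se = math.sqrt(7.0 / outside.size)
        assert abs(outside.mean() - 7.0) < 3 * se

    def test_compound_het_half_depth_unique_zero_shared(self, model):
        track = simulate_depth(model, make_case("c2", (DEL1, DEL2)), seed=2)
        us, ue = model.del1_unique
        se = math.sqrt(3.5 / (ue - us))
        assert abs(track.depth[us:ue].mean() - 3.5) < 3 * se
        ss, sse = model.shared
        assert np.all(track.depth[ss:sse] == 0)

    @pytest.mark.parametrize("coverage", [1.0, 7.0, 56.0])
    def test_wt_mean_depth_matches_coverage(self, model, coverage):
        spec = make_case("w", (WT, WT), coverage=coverage)
        track = simulate_depth(model, spec, seed=3)
        se = math.sqrt(coverage / model.region_length)
        assert abs(track.depth.mean() - coverage) < 3 * se
        assert track.background_mean == coverage

    def test_pool_expected_copy_number_from_members(self, model):
        # 21 members, 7 of them Del1/WT: mean CN over the Del1-unique segment
        # is (14*2 + 7*1)/21 = 5/3, so expected depth is 56 * (5/6) = 46.67.
        members = tuple([(DEL1, WT)] * 7 + [(WT, WT)] * 14)
        pool = SampleSpec("p", 56.0, is_pool=True, pool_members=members)
        track = simulate_depth(model, pool, seed=4)
        us, ue = model.del1_unique
        expect = 56.0 * (5 / 3) / 2
        se = math.sqrt(expect / (ue - us))
        assert abs(track.depth[us:ue].mean() - expect) < 3 * se

    def test_mapping_noise_zero_gives_exact_zero(self, model):
        track = simulate_depth(model, make_case("c", (DEL1, DEL1)), seed=5, mapping_noise=0.0)
        lo, hi = model.del1
        assert track.depth[lo:hi].sum() == 0
        noisy = simulate_depth(model, make_case("c", (DEL1, DEL1)), seed=5, mapping_noise=0.5)
        assert noisy.depth[lo:hi].sum() > 0

    def test_softclip_enriched_only_with_junction(self, model):
        carrier = simulate_depth(model, make_case("c", (DEL1, WT)), seed=6)
        wt = simulate_depth(model, make_case("w", (WT, WT)), seed=6)
        bp1 = model.breakpoints["BP1"]
        win = slice(bp1 - 500, bp1 + 500)
        carrier_rate = carrier.softclip[win].sum() / max(1, carrier.depth[win].sum())
        wt_rate = wt.softclip[win].sum() / max(1, wt.depth[win].sum())
        assert carrier_rate > 5 * wt_rate
        assert np.all(carrier.softclip <= carrier.depth)

    def test_byte_identical_under_fixed_seed(self, model):
        a = simulate_depth(model, make_case("c", (DEL1, DEL2)), seed=9)
        b = simulate_depth(model, make_case("c", (DEL1, DEL2)), seed=9)
        np.testing.assert_array_equal(a.depth, b.depth)
        np.testing.assert_array_equal(a.softclip, b.softclip)


def _flat_model(freqs, founder_alt=None, region_length=300_000):
    freqs = np.asarray(freqs, dtype=float)
    n = len(freqs)
    pos = np.linspace(10_000, region_length - 10_000, n).astype(np.int64)
    return RegionModel(
        region_length=region_length,
        del1=(65_000, 235_000),
        del2=(165_000, 235_000),
        snp_positions=pos,
        snp_alt_freqs=freqs,
        founder_alt=np.zeros(n, dtype=np.int8) if founder_alt is None else np.asarray(founder_alt, dtype=np.int8),
    )


class TestPoolSnpCounts:
    def test_all_ref_members_no_error_yield_zero_alt(self):
        m = _flat_model(np.zeros(50))
        counts = simulate_pool_snp_counts(m, [(WT, WT)] * 21, coverage=56.0, error_rate=0.0, seed=1)
        assert counts["alt_count"].sum() == 0
        assert counts["ref_count"].sum() > 0

    def test_half_frequency_site_converges(self):
        # Del2/WT members at a Del1-unique site: the Del2 haplotype carries the
        # founder alt allele, the WT haplotype is reference => pooled p = 0.5.
        m = _flat_model(np.zeros(5), founder_alt=np.ones(5))
        counts = simulate_pool_snp_counts(m, [(DEL2, WT)] * 21, coverage=5_000.0, seed=2)
        unique = counts[(counts["position"] >= 65_000) & (counts["position"] < 165_000)]
        depth = (unique["ref_count"] + unique["alt_count"]).sum()
        frac = unique["alt_count"].sum() / depth
        se = math.sqrt(0.25 / depth)
        assert abs(frac - 0.5) < 3 * se

    def test_pooled_frequency_is_mean_member_dosage(self):
        # Brute-force enumeration over member haplotypes with deterministic
        # alleles (founder alt, population frequency 0): at a shared-region
        # site only WT haplotypes remain and all are ref; at a Del1-unique
        # site Del2 haplotypes add founder alts.
        members = [(DEL1, WT), (DEL2, WT), (WT, WT), (DEL2, DEL2)]
        m = _flat_model(np.zeros(7), founder_alt=np.ones(7))
        counts = simulate_pool_snp_counts(m, members, coverage=20_000.0, seed=3)
        for _, row in counts.iterrows():
            pos = row["position"]
            present_alt = present = 0
            for pair in members:
                for hap in pair:
                    here = bool(m.haplotype_present(hap, np.array([pos]))[0])
                    present += here
                    present_alt += here and hap in (DEL1, DEL2)
            depth = row["ref_count"] + row["alt_count"]
            expected = present_alt / present
            se = math.sqrt(max(expected * (1 - expected), 1e-9) / depth)
            assert abs(row["alt_count"] / depth - expected) <= max(3 * se, 1e-12)

    def test_error_rate_injects_discordant_reads(self):
        m = _flat_model(np.zeros(200))
        counts = simulate_pool_snp_counts(m, [(WT, WT)] * 10, coverage=100.0, error_rate=0.01, seed=4)
        total = (counts["ref_count"] + counts["alt_count"]).sum()
        frac = counts["alt_count"].sum() / total
        se = math.sqrt(0.01 * 0.99 / total)
        assert abs(frac - 0.01) < 4 * se

    def test_empty_member_list_rejected(self, model):
        with pytest.raises(ValueError):
            simulate_pool_snp_counts(model, [], coverage=10.0)

    def test_fully_deleted_sites_have_no_reads(self):
        m = _flat_model(np.full(20, 0.5))
        counts = simulate_pool_snp_counts(m, [(DEL1, DEL1)] * 3, coverage=50.0, seed=5)
        inside = counts[(counts["position"] >= 65_000) & (counts["position"] < 235_000)]
        assert (inside["ref_count"] + inside["alt_count"]).sum() == 0


class TestSimulateDdpcr:
    def test_wt_reference_and_target_symmetry(self):
        n = 100_000
        ref = simulate_ddpcr((WT, WT), "reference", total_droplets=n, seed=1)
        tgt = simulate_ddpcr((WT, WT), "shared_region", total_droplets=n, seed=2)
        p = 1 - math.exp(-1.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(ref.positive_droplets / n - tgt.positive_droplets / n) < 6 * se

    def test_hom_del1_null_in_unique_region(self):
        a = simulate_ddpcr((DEL1, DEL1), "del1_unique_region", total_droplets=20_000, seed=3)
        assert a.positive_droplets == 0  # default false-positive floor is 0

    def test_hemizygous_poisson_occupancy(self):
        n = 100_000
        a = simulate_ddpcr((DEL1, WT), "del1_unique_region", total_droplets=n,
                           mean_copies_per_droplet_ref=1.0, seed=4)
        p = 1 - math.exp(-0.5)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(a.positive_droplets / n - p) < 3 * se

    def test_positive_fraction_monotone_in_copy_number(self):
        fractions = []
        for pair, target in [((DEL1, DEL1), "del1_unique_region"),
                             ((DEL1, WT), "del1_unique_region"),
                             ((WT, WT), "del1_unique_region")]:
            a = simulate_ddpcr(pair, target, total_droplets=50_000, seed=5)
            fractions.append(a.positive_droplets / a.total_droplets)
        assert fractions[0] < fractions[1] < fractions[2]

    @pytest.mark.parametrize(
        "pair, target, cn",
        [
            ((WT, WT), "reference", 2),
            ((DEL1, DEL2), "del1_unique_region", 1),
            ((DEL1, DEL2), "shared_region", 0),
            ((DEL2, DEL2), "del1_unique_region", 2),
            ((DEL2, WT), "shared_region", 1),
        ],
    )
    def test_target_copy_number_table(self, pair, target, cn):
        assert target_copy_number(pair, target) == cn

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError):
            simulate_ddpcr((WT, WT), "reference", mean_copies_per_droplet_ref=-1.0)

    def test_cohort_table_deterministic(self):
        genos = {"a": (DEL1, WT), "b": (WT, WT)}
        assays = [("ref", "reference"), ("u", "del1_unique_region")]
        x = simulate_cohort_ddpcr(genos, assays, seed=6)
        y = simulate_cohort_ddpcr(genos, assays, seed=6)
        assert x.equals(y)


class TestSimulatePopulation:
    def test_zero_frequencies_all_wildtype(self):
        specs = simulate_population(50, 0.0, 0.0, seed=1)
        assert all(s.haplotypes == (WT, WT) for s in specs)

    def test_hwe_carrier_fraction(self):
        q1, q2 = 0.0479, 0.0106
        n = 100_000
        specs = simulate_population(n, q1, q2, seed=2)
        p = 1 - q1 - q2
        expected = 2 * p * (q1 + q2)
        carriers = sum(1 for s in specs if sorted(s.haplotypes) in ([DEL1, WT], [DEL2, WT]))
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(carriers / n - expected) < 3 * se

    def test_seed_reproducibility(self):
        a = simulate_population(100, 0.1, 0.05, seed=3)
        b = simulate_population(100, 0.1, 0.05, seed=3)
        assert [s.haplotypes for s in a] == [s.haplotypes for s in b]

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(10, 0.7, 0.5)
        with pytest.raises(ValueError):
            simulate_population(10, -0.1, 0.0)
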