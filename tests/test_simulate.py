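"""Generator and treatment-operator behaviour."""

import numpy as np
import pandas as pd
import pytest

from protectseq import presets, simulate
from protectseq.simulate import (
    ConfigurationError,
    Fragment,
    FragmentPool,
    GenerationError,
    GeneratorConfig,
    TreatmentSpec,
    apply_treatment,
    initial_pool,
    sample_libraries,
)


def small_config(**kw):
    kw.setdefault("seed", 1)
    kw.setdefault("depth", 10_000)
    return GeneratorConfig(**kw)


class TestBuildReference:
    def test_deterministic_for_seed(self):
        cfg = small_config()
        ref1, sp1 = simulate.build_reference(cfg)
        ref2, sp2 = simulate.build_reference(cfg)
        assert ref1.chromosomes == ref2.chromosomes
        assert [s.species_id for s in sp1] == [s.species_id for s in sp2]
        assert [s.sequence for s in sp1] == [s.sequence for s in sp2]
        ref3, _ = simulate.build_reference(small_config(seed=7))
        assert ref3.chromosomes != ref1.chromosomes

    def test_compartment_fractions_sum_to_one(self):
        _, species = simulate.build_reference(small_config())
        for sp in species:
            assert abs(sum(sp.compartment_fracs) - 1.0) < 1e-9

    def test_default_preset_category_inventory(self):
        ref, species = simulate.build_reference(small_config())
        cats = {sp.category for sp in species}
        assert len(cats) == 11
        assert cats == set(simulate.CATEGORIES)
        assert len(ref.circles) >= 5
        # tiny-RNA producing loci (10-17 nt products) in every category
        for cat in simulate.CATEGORIES:
            ty = [sp for sp in species if sp.category == cat and 10 <= sp.length <= 17]
            assert ty, f"no tiny-RNA species in {cat}"
        feat_ids = {f.feature_id for f in ref.features}
        assert all(sp.source_feature in feat_ids for sp in species)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate.build_reference(GeneratorConfig(preset="nope"))
        with pytest.raises(ConfigurationError):
            presets.make_config("nope")

    def test_species_sequences_are_genomic(self):
        ref, species = simulate.build_reference(small_config())
        feats = {f.feature_id: f for f in ref.features}
        for sp in species[:50]:
            f = feats[sp.source_feature]
            window = ref.fetch(f.chrom, f.start, f.end, "+")
            probe = sp.sequence if f.strand == "+" else simulate.revcomp(sp.sequence)
            assert probe in window


@pytest.fixture(scope="module")
def default_pool():
    cfg = small_config()
    ref, species = simulate.build_reference(cfg)
    return species, initial_pool(species, cfg.read_length)


class TestApplyTreatment:
    def test_control_is_identity(self, default_pool):
        _, pool = default_pool
        out = apply_treatment(pool, TreatmentSpec.named("C"))
        assert out.entries == pool.entries

    def test_unknown_treatment_rejected(self, default_pool):
        _, pool = default_pool
        with pytest.raises(ConfigurationError):
            apply_treatment(pool, TreatmentSpec("X", degrade_linear=False))
        with pytest.raises(ConfigurationError):
            TreatmentSpec.named("RNaseQ")

    def test_rnase_a_footprints_protected_poliv(self):
        frag = Fragment("p1", "outside_protected", "A" * 31, 31, False, 1.0,
                        "footprint", (16, 17))
        out = apply_treatment(FragmentPool([frag]), TreatmentSpec.named("R"))
        assert out.entries, "footprinted fragment should survive as its footprint"
        assert all(e.length in (16, 17) for e in out.entries)
        assert all(len(e.sequence) == e.length for e in out.entries)
        # weight is conserved and split evenly between the two footprint lengths
        assert out.total_weight == pytest.approx(1.0)
        per_len = pd.Series([e.weight for e in out.entries],
                            index=[e.length for e in out.entries]).groupby(level=0).sum()
        assert per_len[16] == pytest.approx(per_len[17])

    def test_rnase_a_removes_naked_keeps_vesicle_cargo(self):
        naked = Fragment("m1", "outside_naked", "A" * 21, 21, False, 1.0)
        inside = Fragment("m2", "inside_EV", "C" * 21, 21, False, 1.0)
        out = apply_treatment(FragmentPool([naked, inside]), TreatmentSpec.named("R"))
        assert [e.species_id for e in out.entries] == ["m2"]

    def test_trypsin_rnase_spares_only_vesicle_cargo(self):
        ty = Fragment("ty1", "inside_EV", "A" * 12, 12, False, 1.0)
        prot = Fragment("p1", "outside_protected", "C" * 21, 21, False, 1.0)
        out = apply_treatment(FragmentPool([ty, prot]), TreatmentSpec.named("TR"))
        assert [e.species_id for e in out.entries] == ["ty1"]
        assert out.entries[0].length == 12

    def test_rnase_r_keeps_only_circles_at_zero_escape(self, default_pool):
        _, pool = default_pool
        rr = TreatmentSpec.named("RR", linear_escape_prob=0.0)
        out = apply_treatment(pool, rr)
        assert out.entries and all(e.circular_origin for e in out.entries)

    def test_treatment_survival_monotonicity(self, default_pool):
        """Per species, surviving weight under TR <= R <= C."""
        _, pool = default_pool

        def by_species(p):
            s = {}
            for e in p.entries:
                s[e.species_id] = s.get(e.species_id, 0.0) + e.weight
            return s

        c = by_species(apply_treatment(pool, TreatmentSpec.named("C")))
        r = by_species(apply_treatment(pool, TreatmentSpec.named("R")))
        tr = by_species(apply_treatment(pool, TreatmentSpec.named("TR")))
        for sp, wc in c.items():
            assert tr.get(sp, 0.0) <= r.get(sp, 0.0) + 1e-12
            assert r.get(sp, 0.0) <= wc + 1e-12

    def test_vesicle_cargo_survives_every_protection_treatment(self, default_pool):
        _, pool = default_pool
        inside = {(e.species_id, e.sequence): e.weight
                  for e in pool.entries if e.compartment == "inside_EV"}
        for t in ("C", "R", "TR"):
            out = apply_treatment(pool, TreatmentSpec.named(t))
            surv = {(e.species_id, e.sequence): e.weight
                    for e in out.entries if e.compartment == "inside_EV"}
            assert surv == inside


class TestSampleLibraries:
    def test_zero_depth_yields_empty_readsets(self, default_pool):
        _, pool = default_pool
        readsets, truth = sample_libraries(pool, small_config(depth=0))
        assert all(rs.n_reads == 0 for rs in readsets)
        assert (truth.to_numpy() == 0).all()

    def test_empty_pool_with_positive_depth_rejected(self):
        with pytest.raises(GenerationError):
            sample_libraries(FragmentPool([]), small_config(depth=100))

    def test_degenerate_single_species_pool(self):
        frag = Fragment("only", "inside_EV", "ACGTACGTACGTACGTACGTA", 21, False, 1.0)
        readsets, truth = sample_libraries(FragmentPool([frag]),
                                           small_config(depth=1000, n_replicates=1))
        assert readsets[0].n_reads == 1000
        assert set(readsets[0].reads["species_id"]) == {"only"}
        assert truth.loc["only"].iloc[0] == 1000

    def test_quarter_weight_species_within_binomial_envelope(self):
        """weight 0.25, depth 1e5, no overdispersion: count within 5 binomial SD."""
        frags = [Fragment("a", "inside_EV", "A" * 21, 21, False, 0.25),
                 Fragment("b", "inside_EV", "C" * 21, 21, False, 0.75)]
        cfg = small_config(depth=100_000, overdispersion=0.0, n_replicates=3)
        _, truth = sample_libraries(FragmentPool(frags), cfg)
        sd = np.sqrt(100_000 * 0.25 * 0.75)  # ~137
        for c in truth.loc["a"]:
            assert abs(c - 25_000) <= 5 * sd

    def test_truth_counts_match_emitted_reads(self, default_pool):
        _, pool = default_pool
        readsets, truth = sample_libraries(pool, small_config(depth=5000, n_replicates=2))
        for rs in readsets:
            assert rs.n_reads == 5000
            pd.testing.assert_series_equal(
                rs.truth_counts().sort_index(),
                truth[rs.sample_id][truth[rs.sample_id] > 0].sort_index(),
                check_names=False)

    def test_replicate_multipliers_shared_across_treatments(self, default_pool):
        """Aliquots of one biological replicate see the same species multipliers."""
        _, pool = default_pool
        cfg = small_config(depth=200_000, n_replicates=2)
        universe = sorted({e.species_id for e in pool.entries})
        rs_c, truth_c = sample_libraries(pool, cfg, "C", species_universe=universe)
        r_pool = apply_treatment(pool, TreatmentSpec.named("R"))
        rs_r, truth_r = sample_libraries(r_pool, cfg, "R", species_universe=universe)

        def weight_by_species(p):
            out = {}
            for e in p.entries:
                out[e.species_id] = out.get(e.species_id, 0.0) + e.weight
            return out

        w_c, w_r = weight_by_species(pool), weight_by_species(r_pool)
        # species sharing compartment fractions share a survival factor; for
        # them the replicate multiplier cancels in the C1/R1 count ratio,
        # leaving only multinomial noise (far below the 22% multiplier CV)
        by_surv: dict[float, list[str]] = {}
        for s, wr in w_r.items():
            if truth_c["C1"].get(s, 0) > 300:
                by_surv.setdefault(round(wr / w_c[s], 6), []).append(s)
        group = max(by_surv.values(), key=len)
        assert len(group) >= 20
        frac_c = truth_c["C1"].loc[group] / truth_c["C1"].sum()
        frac_r = truth_r["R1"].reindex(group).fillna(0) / truth_r["R1"].sum()
        ratio = frac_r.to_numpy() / frac_c.to_numpy()
        assert np.std(ratio) / np.mean(ratio) < 0.10

    def test_compositional_enrichment_of_vesicle_cargo(self):
        """Depleting outside classes raises vesicle-cargo RPM from C to TR."""
        cfg = presets.make_config("default", seed=3, depth=200_000)
        ref, species = simulate.build_reference(cfg)
        pool = initial_pool(species, cfg.read_length)
        universe = [sp.species_id for sp in species]
        _, tc = sample_libraries(pool, cfg, "C", species_universe=universe)
        tr_pool = apply_treatment(pool, TreatmentSpec.named("TR"))
        _, ttr = sample_libraries(tr_pool, cfg, "TR", species_universe=universe)
        inside_heavy = [sp.species_id for sp in species if sp.compartment_fracs[0] >= 0.8]
        rpm_c = (tc.loc[inside_heavy].sum() / tc.sum() * 1e6).to_numpy()
        rpm_tr = (ttr.reindex(inside_heavy).fillna(0).sum() / ttr.sum() * 1e6).to_numpy()
        assert (rpm_tr > rpm_c).all()


class TestConfigValidation:
    def test_negative_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(depth=-1)

    def test_negative_overdispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(overdispersion=-0.1)

    def test_footprint_must_fit_inside_species(self):
        with pytest.raises(GenerationError):
            simulate.RnaSpecies("s", "f", "polIV", 16, False, (0, 1, 0),
                                "footprint", 1.0, "A" * 16, (16, 17))

    def test_circular_species_cannot_footprint(self):
        with pytest.raises(GenerationError):
            simulate.RnaSpecies("s", "f", "circRNA", 30, True, (0, 1, 0),
                                "footprint", 1.0, "A" * 30, (16, 17))
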