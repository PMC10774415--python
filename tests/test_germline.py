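"""Germline cleavage/repair mechanics, analytic oracle and batch kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medflydrive import (
    FEMALE_FERTILITY,
    SSC,
    TRA_HOMING,
    AlleleState,
    DriveParams,
    Genotype,
    Individual,
    Karyotype,
    LocusId,
    Sex,
    apply_maternal_deposition,
    drive_transmission_probability,
    form_gamete,
    gamete_distribution,
    locus_gamete_distribution,
    maternal_tra_provision,
    resolve_germline,
    sample_parent_gametes,
)
from medflydrive.germline import resolve_germline_batch, sample_gametes_batch

A = AlleleState

probs = st.floats(min_value=0.0, max_value=1.0)
pairs = st.tuples(st.sampled_from(list(AlleleState)), st.sampled_from(list(AlleleState)))


def params_of(c, h, r2, k=1.0):
    return DriveParams(cleavage_rate=c, hdr_rate=h, r2_fraction=r2, maternal_factor=k)


class TestDriveParams:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            DriveParams(cleavage_rate=1.2)
        with pytest.raises(ValueError):
            DriveParams(maternal_factor=-0.1)

    def test_maternal_rate_clamped(self):
        assert params_of(0.8, 0.5, 0.5, k=2.0).maternal_cleavage_rate == 1.0
        assert params_of(0.8, 0.5, 0.5, k=0.5).maternal_cleavage_rate == pytest.approx(0.4)


class TestResolveGermline:
    def test_perfect_homing(self, rng):
        assert resolve_germline((A.DRIVE, A.WILD), True, params_of(1, 1, 0.5), rng) == (
            A.DRIVE,
            A.DRIVE,
        )

    def test_no_activity_leaves_pair_unchanged(self, rng):
        assert resolve_germline((A.DRIVE, A.WILD), True, params_of(0, 1, 0.5), rng) == (
            A.DRIVE,
            A.WILD,
        )

    def test_forced_nhej_forced_r2(self, rng):
        assert resolve_germline((A.DRIVE, A.WILD), True, params_of(1, 0, 1), rng) == (
            A.DRIVE,
            A.R2,
        )

    def test_resistance_allele_homing(self, rng):
        """An R allele on the homolog is copied just like the construct."""
        assert resolve_germline((A.R1, A.WILD), False, params_of(1, 1, 0.5), rng) == (
            A.R1,
            A.R1,
        )

    @given(pair=pairs, c=probs, h=probs, r2=probs, seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_non_wild_alleles_never_altered(self, pair, c, h, r2, seed):
        rng = np.random.default_rng(seed)
        out = resolve_germline(pair, True, params_of(c, h, r2), rng)
        assert len(out) == 2
        for before, after in zip(pair, out):
            if before is not A.WILD:
                assert after is before

    @given(c=probs, seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_single_cleavage_with_certain_hdr_never_creates_resistance(self, c, seed):
        # only one cleavable allele, h=1: the homolog template is always used
        rng = np.random.default_rng(seed)
        out = resolve_germline((A.DRIVE, A.WILD), True, params_of(c, 1.0, 1.0), rng)
        assert A.R1 not in out and A.R2 not in out


class TestGameteDistribution:
    def test_mendelian_when_no_cleavage(self):
        dist = locus_gamete_distribution((A.DRIVE, A.WILD), True, params_of(0, 1, 0.5))
        assert dist == {A.DRIVE: pytest.approx(0.5), A.WILD: pytest.approx(0.5)}

    def test_closed_form_hemizygote(self):
        """P(construct) = (1+ch)/2, P(wild) = (1-c)/2, NHEJ split by r2."""
        p = params_of(0.95, 0.95, 0.99)
        dist = locus_gamete_distribution((A.DRIVE, A.WILD), True, p)
        assert dist[A.DRIVE] == pytest.approx(0.95125, abs=1e-12)
        assert dist[A.WILD] == pytest.approx(0.025, abs=1e-12)
        assert dist[A.R2] == pytest.approx(0.0235125, abs=1e-12)
        assert dist[A.R1] == pytest.approx(0.0002375, abs=1e-12)

    def test_double_cleavage_forced_nhej(self):
        # both alleles wild, h=0: each gamete allele is R2 w.p. c*r2
        c, r2 = 0.7, 0.6
        dist = locus_gamete_distribution((A.WILD, A.WILD), False, params_of(c, 0.0, r2))
        assert dist[A.R2] == pytest.approx(c * r2, abs=1e-12)
        assert dist.get(A.WILD, 0.0) == pytest.approx(1 - c, abs=1e-12)

    @given(pair=pairs, c=probs, h=probs, r2=probs, can_home=st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_distribution_normalised(self, pair, c, h, r2, can_home):
        dist = locus_gamete_distribution(pair, can_home, params_of(c, h, r2))
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in dist.values())

    def test_transmission_monotone_in_c_and_h(self):
        grid = np.linspace(0, 1, 11)
        for h in grid:
            t = [
                locus_gamete_distribution((A.DRIVE, A.WILD), True, params_of(c, h, 0.5))[A.DRIVE]
                for c in grid
            ]
            assert np.all(np.diff(t) >= -1e-15)
            for c, ti in zip(grid, t):
                assert ti == pytest.approx(drive_transmission_probability(params_of(c, h, 0.5)))
        for c in grid:
            t = [
                locus_gamete_distribution((A.DRIVE, A.WILD), True, params_of(c, h, 0.5))[A.DRIVE]
                for h in grid
            ]
            assert np.all(np.diff(t) >= -1e-15)

    def test_non_carrier_segregates_mendelian(self):
        geno = Genotype(
            karyotype=Karyotype.XX, alleles={LocusId.FERTILITY_1: (A.R1, A.WILD)}
        )
        dist = gamete_distribution(geno, FEMALE_FERTILITY, params_of(1, 1, 1))
        assert dist[LocusId.FERTILITY_1] == {
            A.R1: pytest.approx(0.5),
            A.WILD: pytest.approx(0.5),
        }


def _hemizygous_parent(design, sex=Sex.MALE):
    kary = Karyotype.XY if sex is Sex.MALE else Karyotype.XX
    alleles = {l: (A.WILD, A.WILD) for l in design.loci}
    alleles[design.home_locus] = (A.WILD, A.DRIVE)
    return Individual.develop(Genotype(karyotype=kary, alleles=alleles), True, design)


class TestFormGamete:
    def test_sterile_parent_rejected(self, rng, default_params):
        geno = Genotype(
            karyotype=Karyotype.XX, alleles={LocusId.FERTILITY_1: (A.DRIVE, A.R2)}
        )
        sterile = Individual.develop(geno, True, FEMALE_FERTILITY)
        with pytest.raises(ValueError, match="sterile"):
            form_gamete(sterile, FEMALE_FERTILITY, default_params, rng)

    def test_perfect_drive_always_transmits(self, rng):
        parent = _hemizygous_parent(FEMALE_FERTILITY)
        p = params_of(1, 1, 0.5)
        for _ in range(50):
            g = form_gamete(parent, FEMALE_FERTILITY, p, rng)
            assert g.alleles[LocusId.FERTILITY_1] is A.DRIVE

    def test_mendelian_without_cleavage(self, rng):
        parent = _hemizygous_parent(FEMALE_FERTILITY)
        p = params_of(0, 1, 0.5)
        draws = [
            form_gamete(parent, FEMALE_FERTILITY, p, rng).alleles[LocusId.FERTILITY_1]
            for _ in range(4000)
        ]
        frac = np.mean([d is A.DRIVE for d in draws])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_xx_parent_never_transmits_y(self, rng, default_params):
        mother = _hemizygous_parent(FEMALE_FERTILITY, sex=Sex.FEMALE)
        chroms = {
            form_gamete(mother, FEMALE_FERTILITY, default_params, rng).sex_chromosome
            for _ in range(200)
        }
        assert chroms == {"X"}

    def test_scalar_matches_enumeration(self, rng):
        """Monte Carlo over scalar meioses agrees with the exact distribution."""
        p = params_of(0.8, 0.6, 0.7)
        parent = _hemizygous_parent(SSC)
        n = 20000
        counts = {s: 0 for s in AlleleState}
        for _ in range(n):
            g = form_gamete(parent, SSC, p, rng)
            counts[g.alleles[LocusId.TRA]] += 1
        exact = locus_gamete_distribution((A.WILD, A.WILD), False, p)
        for state, prob in exact.items():
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(counts[state] / n - prob) <= 3 * se + 1e-9


class TestBatchKernels:
    @pytest.mark.parametrize("pair", [(A.DRIVE, A.WILD), (A.WILD, A.WILD), (A.R1, A.WILD)])
    def test_batch_frequencies_match_enumeration(self, pair, rng):
        p = params_of(0.9, 0.7, 0.8)
        n = 100_000
        tiled = np.repeat(np.array([[int(a) for a in pair]], dtype=np.int8), n, axis=0)
        draws = sample_gametes_batch(tiled, True, p, rng)
        exact = locus_gamete_distribution(pair, True, p)
        for state, prob in exact.items():
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(np.mean(draws == int(state)) - prob) <= 3 * se + 1e-9

    def test_batch_preserves_non_wild(self, rng):
        p = params_of(1.0, 0.5, 0.5)
        pairs_arr = np.array([[1, 3], [2, 2], [1, 2]], dtype=np.int8)
        out = resolve_germline_batch(pairs_arr, True, p, rng)
        assert np.array_equal(out, pairs_arr)

    def test_active_mask_blocks_cleavage(self, rng):
        p = params_of(1.0, 0.0, 1.0)
        tiled = np.zeros((500, 2), dtype=np.int8)  # all wild-type parents
        draws = sample_gametes_batch(tiled, True, p, rng, active=np.zeros(500, bool))
        assert np.all(draws == 0)


class TestMaternalDeposition:
    def _zygote(self):
        return Genotype(
            karyotype=Karyotype.XX,
            alleles={LocusId.FERTILITY_1: (A.WILD, A.DRIVE), LocusId.TRA: (A.WILD, A.WILD)},
        )

    def test_no_construct_no_deposition(self, rng):
        z = self._zygote()
        out = apply_maternal_deposition(z, False, SSC, params_of(1, 1, 1), rng)
        assert out.alleles == z.alleles

    def test_zero_maternal_factor_is_inert(self, rng):
        z = self._zygote()
        out = apply_maternal_deposition(z, True, SSC, params_of(1, 1, 1, k=0.0), rng)
        assert out.alleles == z.alleles

    def test_full_deposition_writes_r1_when_r2_zero(self, rng):
        out = apply_maternal_deposition(
            self._zygote(), True, SSC, params_of(1, 1, 0.0, k=1.0), rng
        )
        assert out.alleles[LocusId.FERTILITY_1] == (A.R1, A.DRIVE)
        assert out.alleles[LocusId.TRA] == (A.R1, A.R1)

    @given(c=probs, h=probs, r2=probs, k=st.floats(0, 3), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_deposition_never_creates_drive(self, c, h, r2, k, seed):
        rng = np.random.default_rng(seed)
        z = Genotype(
            karyotype=Karyotype.XX,
            alleles={LocusId.FERTILITY_1: (A.WILD, A.WILD), LocusId.TRA: (A.WILD, A.R2)},
        )
        out = apply_maternal_deposition(z, True, SSC, params_of(c, h, r2, k), rng)
        assert all(A.DRIVE not in pair for pair in out.alleles.values())


class TestMaternalProvision:
    def test_wild_type_mother_always_provides(self, rng, default_params):
        geno = Genotype(
            karyotype=Karyotype.XX,
            alleles={LocusId.FERTILITY_1: (A.WILD, A.WILD), LocusId.TRA: (A.WILD, A.WILD)},
        )
        mother = Individual.develop(geno, True, SSC)
        assert maternal_tra_provision(mother, SSC, default_params, rng) is True

    def test_ssc_mother_with_certain_cleavage_never_provides(self, rng):
        mother = _hemizygous_parent(SSC, sex=Sex.FEMALE)
        assert maternal_tra_provision(mother, SSC, params_of(1, 1, 1), rng) is False

    def test_tra_drive_mother_without_cleavage_provides(self, rng):
        geno = Genotype(
            karyotype=Karyotype.XX, alleles={LocusId.TRA: (A.DRIVE, A.WILD)}
        )
        mother = Individual.develop(geno, True, TRA_HOMING)
        assert maternal_tra_provision(mother, TRA_HOMING, params_of(0, 1, 1), rng) is True

    def test_r1_allele_secures_provision(self, rng):
        """R1 has lost the target site: maternal Cas9 cannot disrupt it."""
        geno = Genotype(
            karyotype=Karyotype.XX,
            alleles={LocusId.FERTILITY_1: (A.WILD, A.DRIVE), LocusId.TRA: (A.R1, A.WILD)},
        )
        mother = Individual.develop(geno, True, SSC)
        assert maternal_tra_provision(mother, SSC, params_of(1, 1, 1), rng) is True

    def test_male_rejected(self, rng, default_params):
        father = _hemizygous_parent(SSC, sex=Sex.MALE)
        with pytest.raises(ValueError, match="mothers"):
            maternal_tra_provision(father, SSC, default_params, rng)

    def test_fertility_only_design_always_provides(self, rng):
        mother = _hemizygous_parent(FEMALE_FERTILITY, sex=Sex.FEMALE)
        assert maternal_tra_provision(mother, FEMALE_FERTILITY, params_of(1, 1, 1), rng) is True


class TestSampleParentGametes:
    def test_transmission_matches_closed_form(self, rng):
        p = params_of(0.95, 0.95, 0.99)
        parent = _hemizygous_parent(FEMALE_FERTILITY)
        n = 50_000
        draws = sample_parent_gametes(parent, FEMALE_FERTILITY, p, n, rng)
        frac = np.mean(draws[LocusId.FERTILITY_1] == int(A.DRIVE))
        expected = drive_transmission_probability(p)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) <= 3 * se
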