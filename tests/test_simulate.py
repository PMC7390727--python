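"""Ground-truth consistency and statistical calibration of the generator."""

import numpy as np
import pytest

from pentacensus import io_tables
from pentacensus.motif import ALPHABET
from pentacensus.pentapeptide import match_cterm_motif
from pentacensus.simulate import (
    CladeSpec,
    default_pentapeptide_pwm,
    generate,
    make_study_config,
    zero_truncated_nb_stats,
)


def one_clade(**overrides):
    spec = dict(
        name="clade",
        rank_path={"superkingdom": "Bacteria", "phylum": "P", "class": "C",
                   "order": "O", "family": "F"},
        n_genomes=20,
        receptor_count_mean=8.0,
        receptor_count_dispersion=1.2,
        pentapeptide_probability=0.3,
        lbd_family_weights={"TarH": 0.2, "CZB": 0.1, "none": 0.7},
        tm_fraction=0.7,
    )
    spec.update(overrides)
    return CladeSpec(**spec)


class TestCladeSpec:
    def test_study_regime_config_validates(self):
        clades = make_study_config(500)
        assert sum(c.n_genomes for c in clades) >= 490
        assert all(0 <= c.pentapeptide_probability <= 1 for c in clades)

    def test_study_regime_prevalence_declines_with_receptor_count(self):
        # the regime that induces the negative pooled-abundance trend
        clades = make_study_config(500)
        p = [c.pentapeptide_probability for c in clades]
        m = [c.receptor_count_mean for c in clades]
        assert np.corrcoef(p, m)[0, 1] < 0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            one_clade(pentapeptide_probability=1.5)

    def test_unknown_lbd_family_rejected(self):
        with pytest.raises(ValueError):
            one_clade(lbd_family_weights={"NotAFamily": 1.0})


class TestGenerate:
    def test_same_seed_gives_byte_identical_bundle(self, tmp_path):
        b1, _ = generate([one_clade()], tmp_path / "a", seed=3)
        b2, _ = generate([one_clade()], tmp_path / "b", seed=3)
        for name in ("fasta", "domains", "tm", "metadata", "habitat", "ground_truth"):
            assert getattr(b1, name).read_bytes() == getattr(b2, name).read_bytes()

    def test_different_seed_differs(self, tmp_path):
        b1, _ = generate([one_clade()], tmp_path / "a", seed=3)
        b2, _ = generate([one_clade()], tmp_path / "b", seed=4)
        assert b1.fasta.read_bytes() != b2.fasta.read_bytes()

    def test_zero_probability_yields_no_pentapeptides(self, tmp_path):
        bundle, truth = generate(
            [one_clade(pentapeptide_probability=0.0)], tmp_path, seed=5
        )
        receptors = [t for t in truth if t.is_chemoreceptor]
        assert receptors and not any(t.has_pentapeptide for t in receptors)
        for rec in io_tables.read_fasta(bundle.fasta):
            if rec.protein_id.split("_")[-1].startswith("r"):
                assert not match_cterm_motif(rec.sequence)

    def test_unit_probability_yields_full_abundance(self, tmp_path):
        bundle, truth = generate(
            [one_clade(pentapeptide_probability=1.0)], tmp_path, seed=5
        )
        receptors = [t for t in truth if t.is_chemoreceptor]
        assert receptors and all(t.has_pentapeptide for t in receptors)
        by_id = {t.protein_id: t for t in truth}
        for rec in io_tables.read_fasta(bundle.fasta):
            if by_id[rec.protein_id].is_chemoreceptor:
                assert rec.sequence.endswith(by_id[rec.protein_id].pentapeptide)

    def test_negative_ctermini_never_match_motif(self, small_bundle):
        bundle, truth = small_bundle
        by_id = {t.protein_id: t for t in truth}
        for rec in io_tables.read_fasta(bundle.fasta):
            t = by_id[rec.protein_id]
            if t.is_chemoreceptor and not t.has_pentapeptide:
                assert not match_cterm_motif(rec.sequence)

    def test_pwm_violating_aromatic_constraint_rejected(self, tmp_path):
        pwm = default_pentapeptide_pwm()
        pwm[1] = 1 / 20  # uniform at a constrained position
        with pytest.raises(ValueError, match="F/W/Y"):
            generate([one_clade()], tmp_path, seed=1, pentapeptide_pwm=pwm)

    def test_domain_dropping_hook(self, tmp_path):
        full, _ = generate([one_clade()], tmp_path / "full", seed=9)
        dropped, _ = generate(
            [one_clade()], tmp_path / "drop", seed=9, drop_domain_fraction=0.5
        )
        n_full = len(io_tables.read_domain_table(full.domains))
        n_drop = len(io_tables.read_domain_table(dropped.domains))
        assert n_drop < n_full


class TestCalibration:
    def test_receptor_count_mean_matches_truncated_nb(self, tmp_path):
        mean, dispersion = 13.7, 1.2
        n_genomes = 2000
        clade = one_clade(
            n_genomes=n_genomes,
            receptor_count_mean=mean,
            receptor_count_dispersion=dispersion,
            pentapeptide_probability=0.1,
        )
        _, truth = generate([clade], tmp_path, seed=11, n_background_per_genome=0)
        counts = {}
        for t in truth:
            counts[t.proteome_id] = counts.get(t.proteome_id, 0) + 1
        sample = np.array(list(counts.values()), dtype=float)
        tmean, tsd = zero_truncated_nb_stats(mean, dispersion)
        se = tsd / np.sqrt(n_genomes)
        assert abs(sample.mean() - tmean) < 3 * se

    def test_default_pwm_is_valid_and_biased(self):
        pwm = default_pentapeptide_pwm()
        assert np.allclose(pwm.sum(axis=1), 1.0)
        assert pwm[1, ALPHABET.index("W")] > 0.5
        assert pwm[4, ALPHABET.index("F")] > 0.5

    def test_pentapeptide_slope_induces_count_dependence(self, tmp_path):
        clade = one_clade(
            n_genomes=800,
            receptor_count_mean=15.0,
            pentapeptide_probability=0.3,
            pentapeptide_slope=0.01,
        )
        _, truth = generate([clade], tmp_path, seed=13, n_background_per_genome=0)
        totals, penta = {}, {}
        for t in truth:
            totals[t.proteome_id] = totals.get(t.proteome_id, 0) + 1
            if t.has_pentapeptide:
                penta[t.proteome_id] = penta.get(t.proteome_id, 0) + 1
        small = [p for p in totals if totals[p] <= 10]
        large = [p for p in totals if totals[p] >= 20]
        rate = lambda ids: sum(penta.get(p, 0) for p in ids) / sum(
            totals[p] for p in ids
        )
        assert rate(small) > rate(large)
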