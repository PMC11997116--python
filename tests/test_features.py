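"""Measurement windows: adapter padding, normalization, duplex encoding."""

import numpy as np
import pytest

import smrtmod as sm
from smrtmod.features import (
    DUPLEX_CHANNELS,
    NormalizationSpec,
    build_windows,
    callable_sites,
    encode_duplex,
    extract_window,
    normalize_by_thymine,
    normalize_median50,
)
from smrtmod.io_smrt import AdapterFlank, MoleculeKinetics


def make_molecule(sequence, ipd_w=None, with_adapters=True, adapter_len=12,
                  **kw):
    """Hand-built molecule with controllable kinetics (default 0.5)."""
    n = len(sequence)
    base = dict(
        molecule_id="hand", sequence=sequence,
        ipd_w=np.full(n, 0.5) if ipd_w is None else np.asarray(ipd_w, float),
        pw_w=np.full(n, 0.5), ipd_c=np.full(n, 0.5), pw_c=np.full(n, 0.5),
        depth_w=3, depth_c=3)
    base.update(kw)
    if with_adapters:
        fl = AdapterFlank("ACGT" * (adapter_len // 4),
                          *(np.full(adapter_len, 0.5) for _ in range(4)))
        base.setdefault("adapter_left", fl)
        base.setdefault("adapter_right", fl)
    return MoleculeKinetics(**base)


def cg_sequence(length, cpg_at, fill="ATTGA"):
    seq = list((fill * (length // len(fill) + 1))[:length])
    for p in cpg_at:
        seq[p], seq[p + 1] = "C", "G"
    return "".join(seq)


class TestExtractWindow:
    def test_adapter_padding_near_left_end(self):
        mol = make_molecule(cg_sequence(60, [3]))
        w = extract_window(mol, 3, mod_type="5mC")
        assert w.valid
        ad = w.matrix[:, DUPLEX_CHANNELS.index("adapter")]
        assert ad.sum() == 7 and ad[:7].all()  # 10 - 3 rows from the adapter

    def test_no_adapters_no_call_region(self):
        mol = make_molecule(cg_sequence(60, [3]), with_adapters=False)
        w = extract_window(mol, 3, mod_type="5mC", use_adapters=False)
        assert not w.valid and w.matrix is None
        with pytest.raises(ValueError, match="no-call"):
            w.require_valid()

    def test_interior_window_has_no_adapter_rows(self):
        mol = make_molecule(cg_sequence(60, [30]))
        w = extract_window(mol, 30, mod_type="5mC")
        assert w.valid
        assert w.matrix[:, DUPLEX_CHANNELS.index("adapter")].sum() == 0
        assert np.allclose(w.matrix[:, -1], np.arange(-10, 11) / 10)

    def test_one_hot_rows_sum_to_one(self):
        mol = make_molecule(cg_sequence(60, [30]))
        w = extract_window(mol, 30, mod_type="5mC")
        assert np.allclose(w.matrix[:, 4:8].sum(axis=1), 1.0)

    def test_position_out_of_range(self):
        mol = make_molecule(cg_sequence(30, [10]))
        with pytest.raises(ValueError, match="out of range"):
            extract_window(mol, 99, mod_type="5mC")

    def test_base_mismatch_names_position(self):
        mol = make_molecule(cg_sequence(60, [30]))
        with pytest.raises(ValueError, match="position 31"):
            extract_window(mol, 31, mod_type="5mC")  # the G of the CpG

    @pytest.mark.parametrize("width", [5, 11, 21, 31, 41])
    def test_width_sweep_shapes_and_callability(self, width):
        mol = make_molecule(cg_sequence(80, [2, 40]), adapter_len=20)
        w = extract_window(mol, 40, width=width, mod_type="5mC")
        assert w.matrix.shape == (width, 10)
        assert callable_sites(mol, "5mC", width=width) == [2, 40]


class TestMedian50:
    def test_constant_channel_normalizes_to_one(self):
        mol = make_molecule(cg_sequence(120, [60]), ipd_w=np.full(120, 0.4))
        w = extract_window(mol, 60, mod_type="5mC",
                           norm=NormalizationSpec(mode="median50"))
        # adapters are also 0.5 -> ipd_w span median is 0.4 only if the span
        # stays inside the molecule, which it does at position 60
        assert np.allclose(w.matrix[:, 0], 1.0)

    def test_target_over_flat_background(self):
        ipd = np.full(120, 0.2)
        ipd[60] = 0.8
        mol = make_molecule(cg_sequence(120, [60]), ipd_w=ipd)
        w = extract_window(mol, 60, mod_type="5mC",
                           norm=NormalizationSpec(mode="median50"))
        assert w.matrix[10, 0] == pytest.approx(4.0)

    def test_epsilon_floor_and_clamp(self):
        ipd = np.zeros(120)
        ipd[60] = 0.3
        mol = make_molecule(cg_sequence(120, [60]), ipd_w=ipd,
                            with_adapters=False)
        w = extract_window(mol, 60, mod_type="5mC", use_adapters=False,
                           norm=NormalizationSpec(mode="median50",
                                                  epsilon=1e-3))
        assert w.matrix[10, 0] == 10.0  # 0.3/1e-3 = 300, clamped to 10
        assert np.all(w.matrix[:, :4] <= 10.0)

    def test_identity_channels_untouched(self):
        mol = make_molecule(cg_sequence(120, [60]))
        raw = extract_window(mol, 60, mod_type="5mC")
        normed = normalize_median50(raw, mol, NormalizationSpec(mode="median50"))
        assert np.array_equal(raw.matrix[:, 4:], normed.matrix[:, 4:])

    def test_scale_invariance(self):
        mol = make_molecule(cg_sequence(120, [60]),
                            ipd_w=0.2 + 0.3 * np.random.default_rng(0).random(120))
        spec = NormalizationSpec(mode="median50")
        w1 = extract_window(mol, 60, mod_type="5mC", norm=spec)
        for c in (0.1, 3.7, 250.0):
            w2 = extract_window(mol.scaled(c), 60, mod_type="5mC", norm=spec)
            assert np.allclose(w1.matrix, w2.matrix, atol=1e-9)


class TestThymineMedian:
    def _mol(self):
        # A at even, T at odd positions; thymine IPD 0.2, adenine IPD 0.8
        seq = "AT" * 30
        ipd = np.where(np.arange(60) % 2 == 0, 0.8, 0.2)
        return make_molecule(seq, ipd_w=ipd, with_adapters=False)

    def test_adenine_over_thymine_median(self):
        mol = self._mol()
        w = extract_window(mol, 30, strand_mode="watson", mod_type="6mA",
                           use_adapters=False,
                           norm=NormalizationSpec(mode="thymine-median"))
        assert w.matrix[10, 0] == pytest.approx(4.0)  # 0.8 / 0.2

    def test_confounder_set_to_exactly_one(self):
        mol = self._mol()
        spec = NormalizationSpec(mode="thymine-median",
                                 confounder_positions=frozenset({32}))
        w = extract_window(mol, 30, strand_mode="watson", mod_type="6mA",
                           use_adapters=False, norm=spec)
        assert w.matrix[12, 0] == 1.0 and w.matrix[12, 1] == 1.0
        assert w.matrix[10, 0] == pytest.approx(4.0)  # target never masked

    def test_target_in_confounder_set_not_masked(self):
        mol = self._mol()
        spec = NormalizationSpec(mode="thymine-median",
                                 confounder_positions=frozenset({30, 32}))
        w = extract_window(mol, 30, strand_mode="watson", mod_type="6mA",
                           use_adapters=False, norm=spec)
        assert w.matrix[10, 0] == pytest.approx(4.0)

    def test_no_thymine_in_molecule_rejected(self):
        mol = make_molecule("AC" * 30, with_adapters=False)
        with pytest.raises(ValueError, match="thymine"):
            extract_window(mol, 30, strand_mode="watson", mod_type="6mA",
                           use_adapters=False,
                           norm=NormalizationSpec(mode="thymine-median"))

    def test_duplex_mode_rejected(self):
        mol = self._mol()
        with pytest.raises(ValueError, match="strand-specific"):
            build_windows(mol, [30], mod_type=None, strand_mode="duplex",
                          norm=NormalizationSpec(mode="thymine-median"))

    def test_separate_divisors_per_channel(self):
        seq = "AT" * 30
        ipd = np.where(np.arange(60) % 2 == 0, 0.8, 0.2)
        pw = np.where(np.arange(60) % 2 == 0, 0.9, 0.3)
        mol = make_molecule(seq, ipd_w=ipd, pw_w=pw, with_adapters=False)
        w = extract_window(mol, 30, strand_mode="watson", mod_type="6mA",
                           use_adapters=False,
                           norm=NormalizationSpec(mode="thymine-median"))
        assert w.matrix[10, 0] == pytest.approx(4.0)
        assert w.matrix[10, 1] == pytest.approx(3.0)


class TestCallableSites:
    def test_no_call_region_without_adapters(self):
        mol = make_molecule(cg_sequence(100, [3, 50]), with_adapters=False)
        assert callable_sites(mol, "5mC", use_adapters=False) == [50]

    def test_adapters_make_all_sites_callable(self):
        mol = make_molecule(cg_sequence(100, [3, 50]))
        assert callable_sites(mol, "5mC", use_adapters=True) == [3, 50]

    def test_no_cpg_empty(self):
        mol = make_molecule("ATTA" * 25, with_adapters=False)
        assert callable_sites(mol, "5mC") == []

    def test_simulated_library_fully_callable_with_adapters(self):
        mols, _ = sm.simulate_dataset(sm.SimConfig(
            n_molecules=10, seed=17, depth_mean=2, edge_cpg=True))
        for m in mols:
            assert (callable_sites(m, "5mC", use_adapters=True)
                    == sm.target_positions(m, "5mC"))


class TestDuplexEncoding:
    def test_encode_duplex_matches_direct_extraction(self):
        mols, _ = sm.simulate_dataset(sm.SimConfig(n_molecules=1, seed=19,
                                                   depth_mean=3))
        mol = mols[0]
        pos = sm.target_positions(mol, "5mC")[1]
        ww = extract_window(mol, pos, strand_mode="watson")
        wc = extract_window(mol, pos, strand_mode="crick")
        duplex = encode_duplex(ww, wc)
        direct = extract_window(mol, pos, strand_mode="duplex", mod_type="5mC")
        assert np.allclose(duplex.matrix, direct.matrix)

    def test_zero_depth_strand_directs_to_single_mode(self):
        mols, _ = sm.simulate_dataset(sm.SimConfig(n_molecules=1, seed=19,
                                                   depth_mean=3))
        mol = mols[0]
        pos = sm.target_positions(mol, "5mC")[1]
        ww = extract_window(mol, pos, strand_mode="watson")
        wc = extract_window(mol, pos, strand_mode="crick")
        object.__setattr__(ww, "depths", (mol.depth_w, 0))
        object.__setattr__(wc, "depths", (mol.depth_w, 0))
        with pytest.raises(ValueError, match="watson-only"):
            encode_duplex(ww, wc)

    def test_reverse_complement_swaps_kinetic_channels(self):
        # the Crick channel of a duplex window equals the Watson channel of
        # the same window extracted from the reverse-complemented molecule
        mols, _ = sm.simulate_dataset(sm.SimConfig(n_molecules=1, seed=23,
                                                   depth_mean=3))
        mol = mols[0]
        pos = sm.target_positions(mol, "5mC")[1]
        w = extract_window(mol, pos, strand_mode="duplex", mod_type="5mC")
        rc = mol.reverse_complement()
        w_rc = extract_window(rc, len(mol) - 1 - pos, strand_mode="duplex")
        assert np.allclose(w.matrix[:, 2], w_rc.matrix[::-1, 0])
        assert np.allclose(w.matrix[:, 0], w_rc.matrix[::-1, 2])


class TestBatchConsistency:
    def test_batch_equals_single_site_extraction(self):
        mols, _ = sm.simulate_dataset(sm.SimConfig(n_molecules=2, seed=29,
                                                   depth_mean=4))
        spec = NormalizationSpec(mode="median50")
        for mol in mols:
            positions = sm.target_positions(mol, "5mC")
            X, valid = build_windows(mol, positions, mod_type="5mC",
                                     strand_mode="duplex", norm=spec)
            for i, p in enumerate(positions):
                w = extract_window(mol, p, mod_type="5mC", norm=spec)
                assert valid[i] == w.valid
                if w.valid:
                    assert np.allclose(X[i], w.matrix)
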