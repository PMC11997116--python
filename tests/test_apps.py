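"""Downstream applications: end profiles, periodicity, motifs, origin scores."""

import numpy as np
import pytest

import smrtmod as sm
from smrtmod.apps import (
    ReferencePanel,
    anchor_periodicity,
    jagged_end_profile,
    molecule_origin_score,
    motif_enrichment,
)
from smrtmod.calling import MoleculeMethylationProfile
from smrtmod.io_smrt import ModificationCall


def _call(mid, pos, strand, label, mod="6mA", score=None):
    if score is None:
        score = {"modified": 0.9, "unmodified": 0.1, "no_call": None}[label]
    return ModificationCall(mid, pos, strand, mod, score, label, 3)


class TestJaggedEndProfile:
    def _library(self):
        mols, truth = sm.simulate_jagged_library(sm.SimConfig(
            rule="jagged", n_molecules=40, jag_min=5, jag_max=5,
            length_mean=80, length_sd=0, seed=71, depth_mean=2))
        return mols, truth

    def test_truth_based_profile_steps_at_jag_length(self):
        mols, truth = self._library()
        calls = []
        for m in mols:
            for strand in ("watson", "crick"):
                mods = truth.positions(m.molecule_id, strand)
                want = "A" if strand == "watson" else "T"
                for i, b in enumerate(m.sequence):
                    if b == want:
                        calls.append(_call(m.molecule_id, i, strand,
                                           "modified" if i in mods
                                           else "unmodified"))
        prof = jagged_end_profile(calls, mols, D=20)
        assert np.nanmin(prof.level[:5]) == 1.0   # inside the jag fill-in
        assert np.nanmax(prof.level[6:]) == 0.0   # beyond it

    def test_counts_conserved(self):
        mols, truth = self._library()
        D = 15
        calls = [_call(m.molecule_id, i, "watson",
                       "modified" if i in truth.positions(m.molecule_id, "watson")
                       else "unmodified")
                 for m in mols for i, b in enumerate(m.sequence) if b == "A"]
        prof = jagged_end_profile(calls, mols, D=D)
        within = sum(1 for c in calls
                     for L in [len(next(m for m in mols
                                        if m.molecule_id == c.molecule_id))]
                     if L - 1 - c.position <= D)
        assert prof.n.sum() == within

    def test_no_call_rows_excluded(self):
        mols, _ = self._library()
        m = mols[0]
        apos = [i for i, b in enumerate(m.sequence) if b == "A"]
        calls = [_call(m.molecule_id, apos[0], "watson", "no_call")]
        prof = jagged_end_profile(calls, [m], D=len(m))
        assert prof.n.sum() == 0


class TestAnchorPeriodicity:
    def _cosine_calls(self, period, span=1000, per_offset=60, base=0.5,
                      amp=0.4):
        calls = []
        anchor = 50000
        for off in range(-span, span + 1, 10):
            p = base + amp * np.cos(2 * np.pi * off / period)
            n_mod = int(round(per_offset * p))
            for i in range(per_offset):
                calls.append(_call("m", anchor + off + 0, "watson",
                                   "modified" if i < n_mod else "unmodified"))
                calls[-1] = ModificationCall("m", anchor + off, "watson",
                                             "6mA",
                                             0.9 if i < n_mod else 0.1,
                                             "modified" if i < n_mod
                                             else "unmodified", 3)
        return calls, [anchor]

    @pytest.mark.parametrize("period", [120, 180, 240])
    def test_pure_cosine_period_recovered(self, period):
        calls, anchors = self._cosine_calls(period)
        prof = anchor_periodicity(calls, anchors, span=1000, bin_size=10)
        assert prof.estimated_period == pytest.approx(period, abs=10)

    def test_flat_profile_period_missing(self):
        rng = np.random.default_rng(5)
        calls = [_call("m", 50000 + int(o), "watson",
                       "modified" if rng.random() < 0.2 else "unmodified")
                 for o in rng.integers(-1000, 1000, 4000)]
        prof = anchor_periodicity(calls, [50000], span=1000, bin_size=10)
        assert prof.estimated_period is None

    def test_periodogram_agrees_with_autocorrelation(self):
        calls, anchors = self._cosine_calls(180)
        a = anchor_periodicity(calls, anchors, method="autocorrelation")
        b = anchor_periodicity(calls, anchors, method="periodogram")
        assert a.estimated_period == pytest.approx(180, abs=10)
        assert b.estimated_period == pytest.approx(180, abs=15)

    def test_too_few_bins_missing(self):
        calls = [_call("m", 50000, "watson", "modified")]
        prof = anchor_periodicity(calls, [50000])
        assert prof.estimated_period is None


class TestMotifEnrichment:
    def _dam_truth_calls(self, n_mol=120, seed=81):
        mols, truth = sm.simulate_dam_genome(sm.SimConfig(
            rule="dam", n_molecules=n_mol, length_mean=300, p_motif=0.95,
            p_bg=0.01, seed=seed, depth_mean=1))
        calls = []
        for m in mols:
            for strand in ("watson", "crick"):
                mods = truth.positions(m.molecule_id, strand)
                want = "A" if strand == "watson" else "T"
                for i, b in enumerate(m.sequence):
                    if b == want:
                        calls.append(_call(m.molecule_id, i, strand,
                                           "modified" if i in mods
                                           else "unmodified"))
        return calls, mols

    def test_gatc_recovered_as_top_motif(self):
        calls, mols = self._dam_truth_calls()
        res = motif_enrichment(calls, mols)
        assert res[0].motif == "GATC" and res[0].a_index == 1
        assert res[0].level_at_motif == pytest.approx(0.95, abs=0.03)

    def test_shuffled_labels_destroy_enrichment(self):
        calls, mols = self._dam_truth_calls()
        rng = np.random.default_rng(0)
        labels = [c.label for c in calls]
        rng.shuffle(labels)
        shuffled = [ModificationCall(c.molecule_id, c.position, c.strand_mode,
                                     c.mod_type, 0.9 if l == "modified" else 0.1,
                                     l, c.depth)
                    for c, l in zip(calls, labels)]
        res = motif_enrichment(shuffled, mols)
        assert all(r.enrichment <= 2.0 for r in res)

    def test_gapped_bipartite_motif_recovered(self):
        rng = np.random.default_rng(9)
        mols, _ = sm.simulate_dataset(sm.SimConfig(
            rule="all-A", p=0.0, n_molecules=500, length_mean=100,
            length_sd=0, seed=91, depth_mean=1, with_adapters=False))
        calls = []
        for m in mols:
            seq = m.sequence
            for i, b in enumerate(seq):
                if b != "A":
                    continue
                planted = (i >= 1 and seq[i - 1] == "C"
                           and seq[i + 9:i + 11] == "TG")
                calls.append(_call(m.molecule_id, i, "watson",
                                   "modified" if planted else "unmodified"))
        res = motif_enrichment(calls, mols, k_range=(4,), gapped=True,
                               gap_range=(6, 10), part_lengths=(2, 3),
                               min_sites=20)
        assert res[0].motif == "CA(N)8TG" and res[0].a_index == 1

    def test_no_called_sites_rejected(self):
        with pytest.raises(ValueError, match="no called"):
            motif_enrichment([], {})


class TestOriginScore:
    def _profile(self, mid, states, positions=None):
        positions = positions or tuple(range(len(states)))
        return MoleculeMethylationProfile(mid, tuple(positions), tuple(states))

    def test_closed_form_fully_methylated(self):
        panel = ReferencePanel({i: 0.9 for i in range(5)},
                               {i: 0.1 for i in range(5)})
        prof = self._profile("m", ["methylated"] * 5)
        res = molecule_origin_score([prof], panel)
        # per-site LLR ln 9 -> logistic(ln 9) = 0.9
        assert res.molecule_scores["m"] == pytest.approx(0.9)

    def test_symmetric_null_scores_half(self):
        panel = ReferencePanel({i: 0.7 for i in range(4)},
                               {i: 0.7 for i in range(4)})
        prof = self._profile("m", ["methylated", "unmethylated"] * 2)
        res = molecule_origin_score([prof], panel)
        assert res.molecule_scores["m"] == pytest.approx(0.5)

    def test_panel_swap_antisymmetry(self):
        rng = np.random.default_rng(13)
        panel = ReferencePanel({i: rng.uniform(0.2, 0.9) for i in range(6)},
                               {i: rng.uniform(0.2, 0.9) for i in range(6)})
        prof = self._profile("m", list(rng.choice(
            ["methylated", "unmethylated"], 6)))
        a = molecule_origin_score([prof], panel).molecule_scores["m"]
        b = molecule_origin_score([prof], panel.swapped()).molecule_scores["m"]
        assert a + b == pytest.approx(1.0)

    def test_min_cpg_and_missing_site_handling(self):
        panel = ReferencePanel({0: 0.9}, {0: 0.1})
        small = self._profile("small", ["methylated"])
        missing = self._profile("miss", ["methylated"], positions=(99,))
        res = molecule_origin_score([small, missing], panel, min_cpg=1)
        assert "small" in res.molecule_scores
        assert "miss" not in res.molecule_scores
        assert res.n_molecules_excluded == 1 and res.n_sites_skipped == 1
        res2 = molecule_origin_score([small], panel, min_cpg=2)
        assert res2.n_molecules_used == 0 and res2.sample_score is None

    def test_two_population_sample_separation(self):
        # tumor-like vs background mixtures separate at the sample level,
        # better with many-CpG molecules than few-CpG ones
        rng = np.random.default_rng(17)
        sites = list(range(40))
        pa = {i: rng.uniform(0.6, 0.9) for i in sites}
        pb = {i: rng.uniform(0.1, 0.4) for i in sites}
        panel = ReferencePanel(pa, pb)

        def sample(cls, n_mol, n_cpg, seed):
            r = np.random.default_rng(seed)
            profs = []
            probs = pa if cls else pb
            for k in range(n_mol):
                pos = tuple(sorted(r.choice(sites, n_cpg, replace=False)))
                states = tuple("methylated" if r.random() < probs[p]
                               else "unmethylated" for p in pos)
                profs.append(MoleculeMethylationProfile(f"m{k}", pos, states))
            return molecule_origin_score(profs, panel).sample_score

        for n_cpg, floor in ((8, 0.95), (3, 0.80)):
            scores = np.array([sample(c, 50, n_cpg, 100 + i)
                               for i, c in enumerate([0] * 15 + [1] * 15)])
            labels = np.array([0] * 15 + [1] * 15)
            auc = sm.roc_auc(scores, labels)
            if n_cpg == 8:
                auc_many = auc
            assert auc >= floor
        assert auc_many >= auc  # >= few-CpG stratum
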