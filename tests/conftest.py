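"""Shared fixtures.

The expensive trained models are session-scoped so that several acceptance
checks can share one training run (the 5mC scorer also serves the
depth-stratification check; the 6mA scorer serves the baseline comparison,
motif, periodicity and jagged-end checks).
"""

from __future__ import annotations

import numpy as np
import pytest

import smrtmod as sm
from smrtmod.features import default_norm, window_dataset


# ---------------------------------------------------------------------------
# Small deterministic molecules for unit tests
# ---------------------------------------------------------------------------

@pytest.fixture()
def simple_molecule():
    """A 120-nt molecule with adapters, CpGs and adenines, depth 5/4."""
    cfg = sm.SimConfig(rule="cpg", mod_type="5mC", p=0.5, n_molecules=1,
                       length_mean=120, length_sd=0, depth_mean=5, seed=42)
    mols, truth = sm.simulate_dataset(cfg)
    return mols[0], truth


class FakeScorer:
    """Deterministic stand-in for a trained model: scores the centre-row IPD
    through a logistic, so calling logic can be tested without training."""

    def __init__(self, mod_type="5mC", strand_mode="duplex", layout="duplex-v1",
                 width=21, midpoint=1.5):
        self.mod_type = mod_type
        self.strand_mode = strand_mode
        self.layout = layout
        self.width = width
        self.midpoint = midpoint

    def predict(self, X, batch_size=512):
        X = np.asarray(X)
        centre = X[:, self.width // 2, 0]
        return 1.0 / (1.0 + np.exp(-4.0 * (centre - self.midpoint)))


@pytest.fixture()
def fake_duplex_scorer():
    return FakeScorer()


@pytest.fixture()
def fake_6mA_scorer():
    return FakeScorer(mod_type="6mA", strand_mode="watson",
                      layout="single-v1", midpoint=2.0)


# ---------------------------------------------------------------------------
# Labelled window sets from paired simulations
# ---------------------------------------------------------------------------

def cpg_pair_windows(n_mol: int, seed: int, *, mod_type="5mC", depth=20,
                     depth_dist="fixed", depth_range=(1, 30),
                     pos_mod_types=None):
    """Windows + labels from a fully modified vs unmodified CpG library pair.

    ``pos_mod_types`` optionally lists modification types pooled into the
    positive class (e.g. 5mC + 5hmC for a total-modified-cytosine task).
    """
    pos_mod_types = pos_mod_types or [mod_type]
    norm = default_norm("5mC")
    mats, labels, depths = [], [], []
    s = seed
    for label, kinds in ((0, [None]), (1, pos_mod_types)):
        for kind in kinds:
            cfg = sm.SimConfig(
                rule="cpg", mod_type=kind or "5mC", p=0.0 if kind is None else 1.0,
                n_molecules=n_mol if kind is None else max(1, n_mol // len(kinds)),
                depth_mean=depth, depth_dist=depth_dist, depth_range=depth_range,
                seed=s)
            s += 1
            mols, _ = sm.simulate_dataset(cfg)
            X, idx = window_dataset(mols, None, mod_type="5mC", norm=norm)
            by_id = {m.molecule_id: m for m in mols}
            mats.append(X)
            labels.append(np.full(X.shape[0], label))
            depths.append(np.array([min(by_id[mid].depth_w, by_id[mid].depth_c)
                                    for mid, _ in idx]))
    return (np.concatenate(mats), np.concatenate(labels).astype(np.int64),
            np.concatenate(depths))


def wga_6mA_windows(n_mol: int, seed: int, *, depth=20,
                    density_mix=((0.5, 1.0), (0.1, 2 / 3), (1.0, 1 / 3),
                                 (0.0, 1 / 3))):
    """Watson-strand 6mA windows (thymine-median normalized, truth-based
    confounder masking) from all-adenine libraries of mixed modification
    density.

    Mixing densities puts *unmodified* adenines that sit inside a modified
    neighbour's kinetic footprint into the training set — the hard negatives
    an all-or-nothing library pair never contains.
    """
    mats, labels = [], []
    for k, (prob, frac) in enumerate(density_mix):
        cfg = sm.SimConfig(rule="all-A", p=prob,
                           n_molecules=max(2, int(round(n_mol * frac))),
                           depth_mean=depth, seed=seed + k)
        mols, truth = sm.simulate_dataset(cfg)
        conf = {mid: frozenset(truth.positions(mid, "watson"))
                for mid in truth.sites}
        X, idx = window_dataset(mols, None, mod_type="6mA",
                                strand_mode="watson",
                                norm=default_norm("6mA"), confounders=conf)
        y = np.array([1 if pos in truth.positions(mid, "watson") else 0
                      for mid, pos in idx], dtype=np.int64)
        mats.append(X)
        labels.append(y)
    return np.concatenate(mats), np.concatenate(labels).astype(np.int64)


# ---------------------------------------------------------------------------
# Session-scoped trained models
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def mc5_model():
    """Default scorer trained on ~20k simulated 5mC windows at depth 20."""
    X, y, _ = cpg_pair_windows(760, seed=1000)
    model = sm.build_model(layout="duplex-v1", mod_type="5mC", seed=0)
    model, history = sm.train(model, X, y,
                              sm.TrainConfig(seed=0, max_epochs=8, patience=2))
    return {"model": model, "history": history, "n_windows": X.shape[0]}


@pytest.fixture(scope="session")
def m6a_model():
    """6mA scorer trained on WGA-style all-adenine vs unmodified libraries."""
    X, y = wga_6mA_windows(60, seed=2000)
    model = sm.build_model(layout="single-v1", mod_type="6mA",
                           strand_mode="watson", seed=0)
    model, history = sm.train(model, X, y,
                              sm.TrainConfig(seed=0, max_epochs=8, patience=2))
    return {"model": model, "history": history}


def strong_kinetics(scale: float = 0.05) -> sm.KineticModel:
    """Default baselines with reduced per-site context noise: the
    'strong-effect' regime used by the two-stage resolution experiment."""
    base = sm.KineticModel()
    return sm.KineticModel(
        ipd={b: (loc, scale) for b, (loc, _) in base.ipd.items()},
        pw={b: (loc, scale) for b, (loc, _) in base.pw.items()},
        noise_sigma=base.noise_sigma)


STRONG_DEPTH = 40


@pytest.fixture(scope="session")
def stage_models():
    """Two-stage cytosine scorers (uC-vs-5xC, 5mC-vs-5hmC), trained in the
    strong-effect regime (depth 40, context-noise scale 0.05), with stage
    cutoffs calibrated at the equal-error rate on a held-out library."""
    km = strong_kinetics()
    norm = default_norm("5mC")

    def lib_windows(kind, p, n_mol, seed):
        cfg = sm.SimConfig(rule="cpg", mod_type=kind, p=p, n_molecules=n_mol,
                           depth_mean=STRONG_DEPTH, kinetics=km, seed=seed)
        mols, _ = sm.simulate_dataset(cfg)
        X, _ = window_dataset(mols, None, mod_type="5mC", norm=norm)
        return X

    Xn = lib_windows("5mC", 0.0, 90, 3000)
    Xm1 = lib_windows("5mC", 1.0, 45, 3001)
    Xh1 = lib_windows("5hmC", 1.0, 45, 3002)
    X1 = np.concatenate([Xn, Xm1, Xh1])
    y1 = np.concatenate([np.zeros(len(Xn)), np.ones(len(Xm1) + len(Xh1))])
    s1 = sm.build_model(layout="duplex-v1", mod_type="5xC", seed=0)
    s1, _ = sm.train(s1, X1, y1.astype(np.int64),
                     sm.TrainConfig(seed=0, max_epochs=8, patience=2))

    Xm2 = lib_windows("5mC", 1.0, 120, 3101)
    Xh2 = lib_windows("5hmC", 1.0, 120, 3102)
    X2 = np.concatenate([Xm2, Xh2])
    y2 = np.concatenate([np.zeros(len(Xm2)), np.ones(len(Xh2))])
    s2 = sm.build_model(layout="duplex-v1", mod_type="5hmC", seed=0)
    s2, _ = sm.train(s2, X2, y2.astype(np.int64),
                     sm.TrainConfig(seed=0, max_epochs=16, patience=3))

    def eer_cut(score_pos, score_neg):
        cuts = np.linspace(0.02, 0.98, 193)
        gap = [abs((score_pos <= c).mean() - (score_neg > c).mean())
               for c in cuts]
        return float(cuts[int(np.argmin(gap))])

    Xnc = lib_windows("5mC", 0.0, 25, 3201)
    Xmc = lib_windows("5mC", 1.0, 13, 3202)
    Xhc = lib_windows("5hmC", 1.0, 13, 3203)
    cutoff1 = eer_cut(s1.predict(np.concatenate([Xmc, Xhc])), s1.predict(Xnc))
    cutoff2 = eer_cut(s2.predict(Xhc), s2.predict(Xmc))
    return {"stage1": s1, "stage2": s2, "kinetics": km, "depth": STRONG_DEPTH,
            "cutoff1": cutoff1, "cutoff2": cutoff2}
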