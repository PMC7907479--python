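"""The linear Markovian falling-toast toy model.

A slice of toast starts "butter up" or "butter down" (uniformly at
random), falls, and lands in one of the same two states.  Two parameters
deform the fair-coin (Bernoulli) transition matrix:

* ``u_s`` — asymmetry of the toast (buttering one side): biases the
  outcome toward butter-down regardless of the start, lowering the latent
  entropy (more predictable).
* ``u_h`` — deviation from the memory-erasing table height: couples the
  outcome to the initial state, raising the latent dimension (more
  memory).

The transition matrix (row 1 = final butter-up, row 2 = final
butter-down; columns likewise for the initial state) is

    Lambda = [[0.5 - u_s + u_h, 0.5 - u_s - u_h],
              [0.5 + u_s - u_h, 0.5 + u_s + u_h]]

and only parameter combinations keeping all four entries in [0, 1] are
allowed (|u_s| + |u_h| <= 0.5).  Category 1 is butter-up, category 2 is
butter-down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CategoryAlphabet, PairSample
from .measures import latent_measures
from .reduction import TransitionMatrix

__all__ = [
    "BUTTER_UP",
    "BUTTER_DOWN",
    "ToastParams",
    "SweepResult",
    "toast_transition",
    "sample_toast",
    "sweep_toast",
]

BUTTER_UP = 1
BUTTER_DOWN = 2

_ENTRY_NAMES = [
    ("P[up|up]", "0.5 - u_s + u_h"),
    ("P[up|down]", "0.5 - u_s - u_h"),
    ("P[down|up]", "0.5 + u_s - u_h"),
    ("P[down|down]", "0.5 + u_s + u_h"),
]


def _entries(u_s: float, u_h: float):
    return (
        0.5 - u_s + u_h,
        0.5 - u_s - u_h,
        0.5 + u_s - u_h,
        0.5 + u_s + u_h,
    )


@dataclass(frozen=True)
class ToastParams:
    """Feasible (u_s, u_h) pair; validated so all matrix entries are
    probabilities."""

    u_s: float
    u_h: float

    def __post_init__(self):
        for value, (name, formula) in zip(_entries(self.u_s, self.u_h), _ENTRY_NAMES):
            if not -1e-12 <= value <= 1 + 1e-12:
                raise ValueError(
                    f"infeasible toast parameters (u_s={self.u_s}, u_h={self.u_h}): "
                    f"entry {name} = {formula} = {value:.4g} lies outside [0, 1]"
                )


def toast_transition(params: ToastParams) -> TransitionMatrix:
    """Two-state transition matrix of the falling-toast model."""
    a, b, c, d = _entries(params.u_s, params.u_h)
    L = np.clip(np.array([[a, b], [c, d]]), 0.0, 1.0)
    return TransitionMatrix(Lambda=L)


def sample_toast(params: ToastParams, n_experiments: int, seed: int = 0) -> PairSample:
    """Simulate independent drop experiments.

    Each experiment draws the initial side uniformly, then the landing
    side from the corresponding column of the transition matrix.  The
    experiments are independent pairs, not a time chain.
    """
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    rng = np.random.default_rng(seed)
    L = toast_transition(params).Lambda
    x = rng.integers(0, 2, size=n_experiments)  # 0 = up column, 1 = down column
    p_up = L[0, x]
    y = np.where(rng.random(n_experiments) < p_up, BUTTER_UP, BUTTER_DOWN)
    pairs = np.column_stack([x + 1, y])
    return PairSample(pairs=pairs, alphabet=CategoryAlphabet(n=2))


@dataclass(frozen=True)
class SweepResult:
    """Latent measures over a (u_s, u_h) grid.

    ``S_bar`` and ``K_bar`` are (len(u_h), len(u_s)) arrays, NaN at
    infeasible grid points (|u_s| + |u_h| > 0.5).
    """

    u_s_values: np.ndarray
    u_h_values: np.ndarray
    S_bar: np.ndarray
    K_bar: np.ndarray
    n_experiments: int
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        uu_s, uu_h = np.meshgrid(self.u_s_values, self.u_h_values)
        return pd.DataFrame({
            "us": uu_s.ravel(),
            "uh": uu_h.ravel(),
            "S_bar": self.S_bar.ravel(),
            "K_bar": self.K_bar.ravel(),
        })


def sweep_toast(grid_spec=6, n_experiments: int = 10_000, replicates: int = 1,
                seed: int = 0) -> SweepResult:
    """Measure S_bar and K_bar over a grid of toast parameters.

    ``grid_spec`` is either an integer g (g uniform values of each
    parameter over [0, 0.5]) or a pair of explicit value arrays
    ``(u_s_values, u_h_values)``.  Each feasible grid point is simulated
    ``replicates`` times with ``n_experiments`` drops and the measures are
    averaged; infeasible points are recorded as NaN.
    """
    if isinstance(grid_spec, (int, np.integer)):
        us_vals = np.linspace(0.0, 0.5, int(grid_spec))
        uh_vals = np.linspace(0.0, 0.5, int(grid_spec))
    else:
        us_vals, uh_vals = (np.asarray(v, dtype=float) for v in grid_spec)
    S = np.full((uh_vals.size, us_vals.size), np.nan)
    Kb = np.full_like(S, np.nan)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(us_vals.size * uh_vals.size * replicates))
    for r, uh in enumerate(uh_vals):
        for c, us in enumerate(us_vals):
            child_seeds = [next(children) for _ in range(replicates)]
            if abs(us) + abs(uh) > 0.5 + 1e-12:
                continue
            params = ToastParams(u_s=us, u_h=uh)
            s_acc = k_acc = 0.0
            for cs in child_seeds:
                sub = int(cs.generate_state(1)[0] % (2 ** 31))
                m = latent_measures(sample_toast(params, n_experiments, seed=sub))
                s_acc += m.S_bar
                k_acc += m.K_bar
            S[r, c] = s_acc / replicates
            Kb[r, c] = k_acc / replicates
    return SweepResult(u_s_values=us_vals, u_h_values=uh_vals, S_bar=S, K_bar=Kb,
                       n_experiments=n_experiments, replicates=replicates, seed=seed)
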