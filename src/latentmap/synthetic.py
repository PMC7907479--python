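"""Synthetic image stacks with known latent structure.

Each pixel evolves as an independent Markov chain on a small set of
intensity states under a locally chosen transition matrix, then emits its
state's nominal intensity plus additive Gaussian noise.  Three kinds of
hidden structure can be embedded, mirroring the situations the latent
maps are meant to reveal:

* a boolean **mask** region (e.g. a capillary-like branching network)
  whose pixels follow different dynamics from the background,
* a smooth spatial **gradient** of one toast parameter across columns,
* observation **noise** added before discretization.

State intensities default to consecutive integers (0, 1, ...) while the
default noise standard deviation is 0.1, i.e. states sit 10 noise SDs
apart, so discretization recovers the state sequence reliably; raising
``noise_sd`` probes robustness.  Chains start from their local stationary
distribution to avoid burn-in transients, and everything is reproducible
from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _cc_label
from skimage.morphology import dilation as _dilation, disk, erosion as _erosion

from .pipeline import VideoStack
from .toast import ToastParams, toast_transition

__all__ = [
    "SyntheticSpec",
    "generate_stack",
    "capillary_mask",
    "preset_spec",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic stack.

    ``dynamics_out`` (and ``dynamics_in`` for the masked region) are
    either :class:`ToastParams` or explicit n×n column-stochastic arrays.
    ``gradient_param`` ("u_s" or "u_h") with ``gradient_range = (lo, hi)``
    ramps that toast parameter linearly across columns; it requires toast
    dynamics and is validated for feasibility at every column.
    """

    H: int
    W: int
    T: int
    dynamics_out: object = ToastParams(0.0, 0.0)
    dynamics_in: object | None = None
    mask: np.ndarray | None = None
    gradient_param: str | None = None
    gradient_range: tuple | None = None
    noise_sd: float = 0.1
    levels: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.H, self.W) < 1 or self.T < 2:
            raise ValueError("need H, W >= 1 and T >= 2")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (self.H, self.W):
                raise ValueError("mask shape must be (H, W)")
            object.__setattr__(self, "mask", mask)
            if self.dynamics_in is None:
                raise ValueError("a mask requires dynamics_in")
        if (self.gradient_param is None) != (self.gradient_range is None):
            raise ValueError("gradient_param and gradient_range go together")
        if self.gradient_param is not None:
            if self.gradient_param not in ("u_s", "u_h"):
                raise ValueError("gradient_param must be 'u_s' or 'u_h'")
            for dyn in (self.dynamics_out, self.dynamics_in):
                if dyn is not None and not isinstance(dyn, ToastParams):
                    raise ValueError(
                        "gradients are defined for toast-parameter dynamics only"
                    )
        # validate matrices / params eagerly, including the gradient extremes
        for L in self._matrix_variants():
            _as_matrix(L)

    def _matrix_variants(self):
        variants = []
        for dyn in (self.dynamics_out, self.dynamics_in):
            if dyn is None:
                continue
            if self.gradient_param is not None:
                lo, hi = self.gradient_range
                variants += [_apply_gradient(dyn, self.gradient_param, v)
                             for v in (lo, hi)]
            else:
                variants.append(dyn)
        return variants

    @property
    def n_states(self) -> int:
        return _as_matrix(self.dynamics_out).shape[0]


def _apply_gradient(params: ToastParams, name: str, value: float) -> ToastParams:
    kwargs = {"u_s": params.u_s, "u_h": params.u_h}
    kwargs[name] = value
    return ToastParams(**kwargs)


def _as_matrix(dynamics) -> np.ndarray:
    if isinstance(dynamics, ToastParams):
        return toast_transition(dynamics).Lambda
    L = np.asarray(dynamics, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("dynamics matrix must be square")
    if L.min() < 0 or np.max(np.abs(L.sum(axis=0) - 1)) > 1e-9:
        raise ValueError("dynamics matrix must be column-stochastic")
    return L


def _stationary(L: np.ndarray) -> np.ndarray:
    """A stationary distribution of a column-stochastic matrix (the
    eigenvector of the eigenvalue closest to 1, normalized)."""
    vals, vecs = np.linalg.eig(L)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, idx]))
    s = pi.sum()
    if s == 0:
        return np.full(L.shape[0], 1.0 / L.shape[0])
    return pi / s


def _matrix_field(spec: SyntheticSpec) -> np.ndarray:
    """(H, W, n, n) local transition matrix for every pixel."""
    n = spec.n_states
    field_ = np.empty((spec.H, spec.W, n, n))
    grad_values = None
    if spec.gradient_param is not None:
        lo, hi = spec.gradient_range
        ramp = np.linspace(lo, hi, spec.W) if spec.W > 1 else np.array([lo])
        grad_values = ramp
    for c in range(spec.W):
        def localize(dyn):
            if grad_values is not None and isinstance(dyn, ToastParams):
                dyn = _apply_gradient(dyn, spec.gradient_param, grad_values[c])
            return _as_matrix(dyn)

        out_L = localize(spec.dynamics_out)
        field_[:, c] = out_L
        if spec.mask is not None:
            in_L = localize(spec.dynamics_in)
            field_[spec.mask[:, c], c] = in_L
    return field_


def generate_stack(spec: SyntheticSpec):
    """Simulate the stack; returns ``(VideoStack, ground_truth)``.

    ``ground_truth`` is a dict with the mask (or None) and, when a
    gradient is present, the per-pixel value of the ramped parameter.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_states
    Lfield = _matrix_field(spec)
    H, W, T = spec.H, spec.W, spec.T

    # initial states from each pixel's local stationary law
    flat = Lfield.reshape(H * W, n * n)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    stationary = np.stack([_stationary(u.reshape(n, n)) for u in uniq])
    pix_pi = stationary[inverse]  # (H*W, n)
    u0 = rng.random(H * W)
    state = (u0[:, None] > np.cumsum(pix_pi, axis=1)).sum(axis=1).reshape(H, W)

    # cumulative transition probabilities indexed by current state:
    # cum[r, c, i] = cumulative law of the next state given current state i
    cum = np.cumsum(np.transpose(Lfield, (0, 1, 3, 2)), axis=3)
    states = np.empty((T, H, W), dtype=np.int64)
    states[0] = state
    for t in range(1, T):
        p_cur = np.take_along_axis(
            cum, state[:, :, None, None], axis=2
        )[:, :, 0, :]  # (H, W, n)
        u = rng.random((H, W))
        state = (u[:, :, None] > p_cur).sum(axis=2)
        np.clip(state, 0, n - 1, out=state)
        states[t] = state

    levels = (np.arange(n, dtype=float) if spec.levels is None
              else np.asarray(spec.levels, dtype=float))
    frames = levels[states]
    if spec.noise_sd > 0:
        frames = frames + spec.noise_sd * rng.standard_normal(frames.shape)

    truth = {"mask": spec.mask, "states": states}
    if spec.gradient_param is not None:
        lo, hi = spec.gradient_range
        ramp = np.linspace(lo, hi, W) if W > 1 else np.array([lo])
        truth["param_field"] = np.tile(ramp, (H, 1))
    return VideoStack(frames=frames), truth


def capillary_mask(H: int, W: int, n_branches: int = 6, width: int = 3,
                   seed: int = 0) -> np.ndarray:
    """Random-walk branching skeleton dilated to the given width.

    Branches after the first start from a random point of the existing
    skeleton, giving a connected, capillary-like network.  ``width`` is
    the approximate line width in pixels (even values round down to the
    next odd); ``width=0`` returns an empty mask.  The mask fraction is
    kept below 40% by eroding overly dense results.
    """
    if H < 1 or W < 1:
        raise ValueError("dimensions must be positive")
    mask = np.zeros((H, W), dtype=bool)
    if width <= 0 or n_branches <= 0:
        return mask
    rng = np.random.default_rng(seed)
    skel = np.zeros((H, W), dtype=bool)
    steps = max(8, (H + W) // 2)
    anchors = []
    for b in range(n_branches):
        if anchors and b > 0:
            r, c = anchors[rng.integers(len(anchors))]
            pos = np.array([r, c], dtype=float)
        else:
            pos = np.array([rng.uniform(0, H - 1), rng.uniform(0, W - 1)])
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(steps):
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < H and 0 <= c < W):
                break
            skel[r, c] = True
            anchors.append((r, c))
            angle += rng.normal(0.0, 0.25)
            pos += np.array([np.sin(angle), np.cos(angle)])
    radius = (width - 1) // 2
    mask = _dilation(skel, disk(radius)) if radius > 0 else skel
    while mask.mean() > 0.40:
        eroded = _erosion(mask, disk(1))
        if not eroded.any():
            break
        mask = eroded
    return mask


def preset_spec(name: str, H: int = 64, W: int = 64, T: int = 2000,
                seed: int = 0) -> SyntheticSpec:
    """Canned study conditions.

    * ``uniform`` — Bernoulli dynamics everywhere (exchangeable pixels).
    * ``capillary`` — a hidden branching network with strongly asymmetric
      dynamics (u_s = 0.4) in a Bernoulli background.
    * ``gradient`` — u_s ramping 0 → 0.45 across columns (an entropy
      gradient).
    """
    if name == "uniform":
        return SyntheticSpec(H=H, W=W, T=T, seed=seed)
    if name == "capillary":
        mask = capillary_mask(H, W, seed=seed + 1)
        return SyntheticSpec(H=H, W=W, T=T, mask=mask,
                             dynamics_in=ToastParams(0.4, 0.0),
                             dynamics_out=ToastParams(0.0, 0.0), seed=seed)
    if name == "gradient":
        return SyntheticSpec(H=H, W=W, T=T, gradient_param="u_s",
                             gradient_range=(0.0, 0.45), seed=seed)
    raise ValueError(f"unknown preset {name!r}")


def _connected_components(mask: np.ndarray) -> int:
    """Number of 8-connected components (diagnostic helper)."""
    return int(_cc_label(mask, connectivity=2).max())
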