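"""Pixel-wise latent-measure maps for image stacks.

Reads a time-ordered image stack, discretizes the intensities into one
shared alphabet (uniform bins between the global minimum and maximum, so
entropy scales are comparable across pixels), and computes the latent
entropy S_bar and latent dimension K_bar independently for every pixel —
or for pooled b×b pixel patches, where all member-pixel transition pairs
are concatenated into one sample and every member receives the pooled
values.

Pixels are independent, so the maps can be computed in any order; this
implementation walks the image serially with a progress log.  A per-pixel
cost of O(n^4) in the alphabet size n and O(n^2) memory make full-frame
maps cheap for the small alphabets (n <= 16) typical of discretized
intensity data.

Coordinate convention: row-major, origin at the top-left, maps indexed
[row][column]; external CSV output is 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .core import ContingencyTable, discretize_series
from .measures import latent_measures_from_table

__all__ = [
    "VideoStack",
    "MeasureMap",
    "read_stack",
    "compute_measure_maps",
    "baseline_marginal_entropy_map",
    "write_maps",
]

logger = logging.getLogger(__name__)

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")


@dataclass(frozen=True)
class VideoStack:
    """A (T, H, W) array of scalar intensities plus optional metadata.

    ``frame_interval`` is the time between frames in seconds and
    ``pixel_size`` the physical size of a pixel, both purely informational.
    """

    frames: np.ndarray
    frame_interval: float | None = None
    pixel_size: float | None = None

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array of scalar intensities")
        if frames.shape[0] < 2:
            raise ValueError("need at least two frames")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame intensities must be finite")
        object.__setattr__(self, "frames", frames)

    @property
    def shape(self):
        return self.frames.shape


@dataclass(frozen=True)
class MeasureMap:
    """Per-pixel latent-measure grids.

    ``warnings_map`` flags pixels whose pair count did not exceed
    n_effective², the accuracy condition for the contingency estimate.
    ``meta`` records the run parameters for the manifest.
    """

    S_bar_map: np.ndarray
    K_bar_map: np.ndarray
    n_effective_map: np.ndarray
    warnings_map: np.ndarray
    meta: dict = field(default_factory=dict)


def read_stack(path, frame_interval=None, pixel_size=None) -> VideoStack:
    """Load a multi-page TIFF or a directory of frame images (sorted by
    filename) as a video stack.  Frames must be single-channel."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if len(files) < 2:
            raise ValueError(f"directory {path} holds fewer than two frame images")
        import imageio.v3 as iio

        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    else:
        frames = np.asarray(tifffile.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            "stack must be single-channel; reduce color data to a scalar first"
        )
    return VideoStack(frames=frames.astype(np.float64),
                      frame_interval=frame_interval, pixel_size=pixel_size)


def _stack_codes(stack: VideoStack, n_bins: int):
    """Shared-alphabet discretization of the whole stack.

    Returns ``(n, codes)`` where ``codes[t, r, c] = (j - 1) * n + (i - 1)``
    encodes the transition of pixel (r, c) between frames t and t+1.
    """
    alphabet, flat = discretize_series(stack.frames.ravel(), n_bins=n_bins)
    cats = flat.reshape(stack.frames.shape)
    n = alphabet.n
    codes = (cats[1:] - 1) * n + (cats[:-1] - 1)
    return n, codes


def compute_measure_maps(stack: VideoStack, n_bins: int = 8, patch: int = 1,
                         seed: int = 0) -> MeasureMap:
    """Latent-entropy and latent-dimension maps of an image stack.

    ``patch=1`` treats every pixel independently; ``patch=b>1`` pools the
    transition pairs of each b×b block (edge blocks may be smaller) into a
    single sample whose measures are written to all member pixels.
    """
    if n_bins < 1 or patch < 1:
        raise ValueError("n_bins and patch must be positive")
    T, H, W = stack.shape
    n, codes = _stack_codes(stack, n_bins)
    S_map = np.zeros((H, W))
    K_map = np.zeros((H, W))
    n_eff_map = np.zeros((H, W), dtype=np.int64)
    warn_map = np.zeros((H, W), dtype=bool)

    block_rows = range(0, H, patch)
    total = len(block_rows)
    for bi, r0 in enumerate(block_rows):
        for c0 in range(0, W, patch):
            r1, c1 = min(r0 + patch, H), min(c0 + patch, W)
            block = codes[:, r0:r1, c0:c1].ravel()
            counts = np.bincount(block, minlength=n * n).reshape(n, n)
            table = ContingencyTable(C=counts / block.size, n_pairs=block.size)
            m = latent_measures_from_table(table, seed=seed)
            S_map[r0:r1, c0:c1] = m.S_bar
            K_map[r0:r1, c0:c1] = m.K_bar
            n_eff_map[r0:r1, c0:c1] = m.n_effective
            warn_map[r0:r1, c0:c1] = not m.sample_size_ok
        if total >= 10 and (bi + 1) % max(1, total // 10) == 0:
            logger.info("measure maps: %d/%d block rows done", bi + 1, total)
    meta = {"n_bins": n_bins, "alphabet_size": n, "patch": patch, "seed": seed,
            "T": T, "H": H, "W": W}
    return MeasureMap(S_bar_map=S_map, K_bar_map=K_map, n_effective_map=n_eff_map,
                      warnings_map=warn_map, meta=meta)


def baseline_marginal_entropy_map(stack: VideoStack, n_bins: int = 8) -> np.ndarray:
    """Shannon entropy (nats) of each pixel's marginal category histogram.

    Ignores temporal ordering entirely — shuffling the frames leaves this
    map unchanged — so it serves as the order-blind control against which
    the latent measures' use of temporal structure is demonstrated.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    alphabet, flat = discretize_series(stack.frames.ravel(), n_bins=n_bins)
    cats = flat.reshape(stack.frames.shape)
    T = cats.shape[0]
    n = alphabet.n
    ent = np.zeros(cats.shape[1:])
    for k in range(1, n + 1):
        p = (cats == k).sum(axis=0) / T
        nz = p > 0
        ent[nz] -= p[nz] * np.log(p[nz])
    return ent


def write_maps(maps: MeasureMap, out_prefix) -> list[Path]:
    """Write the maps as 32-bit float TIFFs and CSV matrices plus a JSON
    run manifest.  Returns the list of files written."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, grid in (("Sbar", maps.S_bar_map), ("Kbar", maps.K_bar_map)):
        tif = prefix.parent / f"{prefix.name}_{name}.tif"
        tifffile.imwrite(tif, grid.astype(np.float32))
        csv = prefix.parent / f"{prefix.name}_{name}.csv"
        np.savetxt(csv, grid, fmt="%.9g", delimiter=",")
        written += [tif, csv]
    neff_csv = prefix.parent / f"{prefix.name}_neff.csv"
    np.savetxt(neff_csv, maps.n_effective_map, fmt="%d", delimiter=",")
    written.append(neff_csv)
    manifest = prefix.parent / f"{prefix.name}_manifest.json"
    payload = {"software": "latentmap", "version": __version__,
               "n_warned_pixels": int(maps.warnings_map.sum()), **maps.meta}
    manifest.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    written.append(manifest)
    return written
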