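"""SVD low-rank movie denoising with a pluggable per-component image
denoiser.

Each temporal segment (default 2500 frames) is reshaped to frames x
pixels, decomposed as M = U @ C with U the top-k left singular vectors,
each coefficient row is denoised as a 2-D image, and the segment is
recombined as U @ C_hat.  The default component denoiser is a
deterministic edge-preserving total-variation smoother; pass
``identity_denoiser`` for a pure rank-k projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LowRankDecomposition",
    "svd_lowrank",
    "denoise_movie",
    "identity_denoiser",
    "tv_denoiser",
]


@dataclass
class LowRankDecomposition:
    """Top-k factorization of a movie segment: M ~ U @ C.

    U : (frames, k) semi-unitary temporal components.
    C : (k, pixels) coefficient images (flattened spatial maps).
    """

    U: np.ndarray
    C: np.ndarray
    k: int
    segment_len: int
    frame_shape: tuple

    def reconstruct(self) -> np.ndarray:
        movie = (self.U @ self.C).reshape(self.U.shape[0], *self.frame_shape)
        return movie


def svd_lowrank(movie_segment: np.ndarray, k: int = 5) -> LowRankDecomposition:
    """Rank-k SVD of a T x H x W segment flattened to frames x pixels."""
    seg = np.asarray(movie_segment, dtype=np.float64)
    if seg.ndim != 3:
        raise ValueError("segment must be T x H x W")
    t, h, w = seg.shape
    if k > min(t, h * w):
        raise ValueError(f"k={k} exceeds min(frames, pixels)={min(t, h * w)}")
    m = seg.reshape(t, h * w)
    u, _, _ = np.linalg.svd(m, full_matrices=False)
    U = u[:, :k]
    C = U.T @ m
    return LowRankDecomposition(U=U, C=C, k=k, segment_len=t, frame_shape=(h, w))


def identity_denoiser(img: np.ndarray) -> np.ndarray:
    return img


def tv_denoiser(weight: float = 0.05):
    """Edge-preserving total-variation smoother (Chambolle) factory."""
    from skimage.restoration import denoise_tv_chambolle

    def _denoise(img: np.ndarray) -> np.ndarray:
        scale = float(np.max(np.abs(img)))
        if scale == 0:
            return img
        return denoise_tv_chambolle(img / scale, weight=weight) * scale

    return _denoise


def denoise_movie(movie: np.ndarray, k: int = 5, segment_len: int = 2500,
                  component_denoiser=None) -> np.ndarray:
    """Segment-wise low-rank denoising; segments re-concatenated in order.

    Movies shorter than ``segment_len`` are processed as one short
    segment.  The final partial segment, if any, is processed on its own.
    """
    if component_denoiser is None:
        component_denoiser = tv_denoiser()
    movie = np.asarray(movie, dtype=np.float64)
    t = movie.shape[0]
    out = np.empty_like(movie)
    for start in range(0, t, segment_len):
        seg = movie[start:start + segment_len]
        dec = svd_lowrank(seg, k=min(k, seg.shape[0]))
        c_hat = np.stack([
            component_denoiser(row.reshape(dec.frame_shape)).ravel()
            for row in dec.C
        ])
        out[start:start + segment_len] = (dec.U @ c_hat).reshape(seg.shape)
    return out
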