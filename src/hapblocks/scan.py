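"""Detection of extended-haplotype segments by long-range block-linkage scoring.

For a candidate segment we code, on every chromosome, the local haplotype of
``k`` SNPs just inside each end ("SNP blocks").  If the segment is inherited
as a unit, some chromosomes carry strongly linked (left, right) block pairs;
a two-component mixture of independent-block multinomials then beats the
single-component independence model.  The score is the BIC difference

    ΔBIC = BIC(independence) − BIC(mixture),   BIC = −2·logL + k_params·ln n

and ΔBIC > 0 declares a positive window.  Positive windows across a grid of
window sizes and steps are merged into candidate segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


class ScanError(ValueError):
    pass


def encode_local_haplotypes(gm: GenotypeMatrix, breakpoint_pos: int, side: str, k: int = 2):
    """Dense integer codes of the k-SNP local haplotype beside a breakpoint.

    ``side="left"`` takes the k SNPs with largest position ≤ breakpoint;
    ``side="right"`` the k SNPs with smallest position ≥ breakpoint.
    Chromosomes with any missing allele in the window are excluded.

    Returns ``(codes, valid_mask)`` where ``codes`` has one entry per valid
    chromosome and ``valid_mask`` has one entry per chromosome row of ``gm``.
    """
    pos = gm.positions
    if side == "left":
        idx = np.flatnonzero(pos <= breakpoint_pos)
        if len(idx) < k:
            raise ScanError(f"fewer than {k} SNPs left of {breakpoint_pos}")
        idx = idx[-k:]
    elif side == "right":
        idx = np.flatnonzero(pos >= breakpoint_pos)
        if len(idx) < k:
            raise ScanError(f"fewer than {k} SNPs right of {breakpoint_pos}")
        idx = idx[:k]
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    words = gm.alleles[:, idx]
    valid = (words != MISSING).all(axis=1)
    # map k-allele words to a dense integer alphabet
    _, codes = np.unique(words[valid], axis=0, return_inverse=True)
    return codes, valid


def _loglik_independent(counts: np.ndarray) -> float:
    """Log-likelihood of the independence model from a (L, R) count table."""
    n = counts.sum()
    ll = 0.0
    for marg in (counts.sum(axis=1), counts.sum(axis=0)):
        nz = marg[marg > 0]
        ll += float(np.sum(nz * np.log(nz / n)))
    return ll


def _em_mixture(counts: np.ndarray, rng: np.random.Generator, n_restarts: int = 5,
                tol: float = 1e-6, max_iter: int = 500):
    """Two-component mixture of independent left/right multinomials, by EM.

    Restart 0 starts at the independence solution (a fixed point whose
    likelihood equals the null's), guaranteeing logL(mixture) ≥ logL(null);
    the remaining restarts draw cell responsibilities from a Dirichlet.
    Returns ``(best_loglik, converged)``.
    """
    n = counts.sum()
    L, R = counts.shape
    cells = counts > 0
    N = counts[cells]  # flat nonzero counts
    li, ri = np.nonzero(cells)

    best_ll, any_converged = -np.inf, False
    for restart in range(1 + n_restarts):
        if restart == 0:
            resp = np.full((len(N), 2), 0.5)
        else:
            resp = rng.dirichlet((1.0, 1.0), size=len(N))
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            # M-step
            w = (resp * N[:, None]).sum(axis=0) / n
            a = np.zeros((L, 2))
            b = np.zeros((R, 2))
            np.add.at(a, li, resp * N[:, None])
            np.add.at(b, ri, resp * N[:, None])
            a /= np.maximum(a.sum(axis=0, keepdims=True), 1e-300)
            b /= np.maximum(b.sum(axis=0, keepdims=True), 1e-300)
            # E-step
            comp = np.maximum(w[None, :] * a[li] * b[ri], 1e-300)
            tot = comp.sum(axis=1)
            resp = comp / tot[:, None]
            ll = float(np.sum(N * np.log(tot)))
            if ll - ll_prev < tol:
                converged = True
                break
            ll_prev = ll
        if converged:
            any_converged = True
            best_ll = max(best_ll, ll)
    return best_ll, any_converged


def fit_block_models(left_codes: np.ndarray, right_codes: np.ndarray,
                     n_restarts: int = 5, tol: float = 1e-6,
                     max_iter: int = 500, rng=None):
    """Score long-range linkage between two coded SNP blocks.

    Fits M0 (one component, independent left/right multinomials) and M1
    (two-component mixture of such products, by EM) and returns
    ``(ll_null, ll_mix, bic_diff)`` with
    ``bic_diff = BIC(M0) − BIC(M1) > 0`` flagging excess block linkage.
    """
    if len(left_codes) != len(right_codes):
        raise ScanError("left/right code vectors differ in length")
    rng = np.random.default_rng(rng)
    L = int(left_codes.max()) + 1 if len(left_codes) else 0
    R = int(right_codes.max()) + 1 if len(right_codes) else 0
    if L < 2 or R < 2:
        raise ScanError("need >= 2 distinct codes on each side")
    n = len(left_codes)
    counts = np.zeros((L, R))
    np.add.at(counts, (left_codes, right_codes), 1.0)

    ll0 = _loglik_independent(counts)
    ll1, converged = _em_mixture(counts, rng, n_restarts=n_restarts, tol=tol,
                                 max_iter=max_iter)
    if not converged:
        raise ScanError("EM failed to converge in all restarts")
    p0 = (L - 1) + (R - 1)
    p1 = 2 * ((L - 1) + (R - 1)) + 1
    logn = np.log(n)
    bic_diff = (-2 * ll0 + p0 * logn) - (-2 * ll1 + p1 * logn)
    return ll0, ll1, float(bic_diff)


@dataclass
class ScanResult:
    """All scored breakpoint pairs plus merged positive segments."""

    windows: pd.DataFrame  # left_bp, right_bp, window_size, bic_diff, n_chromosomes
    segments: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["start_bp", "end_bp", "max_bic_diff"]))


def merge_positive_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping ΔBIC-positive windows into candidate segments."""
    pos = windows[windows["bic_diff"] > 0].sort_values("left_bp")
    segments = []
    for row in pos.itertuples(index=False):
        if segments and row.left_bp <= segments[-1][1]:
            segments[-1][1] = max(segments[-1][1], row.right_bp)
            segments[-1][2] = max(segments[-1][2], row.bic_diff)
        else:
            segments.append([row.left_bp, row.right_bp, row.bic_diff])
    return pd.DataFrame(segments, columns=["start_bp", "end_bp", "max_bic_diff"])


def scan_region(gm: GenotypeMatrix, window_sizes_bp: Sequence[int],
                step_bp: Optional[int] = None, k: int = 2,
                seed: Optional[int] = None, n_restarts: int = 5) -> ScanResult:
    """Scan a region for segments with excess long-range block linkage.

    For every window size ``w`` and window start on the step grid, the
    breakpoint pair (start, start + w) is scored with
    :func:`fit_block_models`; the left block is the first k SNPs at or right
    of the start, the right block the last k SNPs at or left of the end
    (both inside the window).  Windows whose blocks overlap, have < k SNPs,
    or show < 2 distinct codes on a side are skipped.
    """
    window_sizes_bp = sorted(int(w) for w in window_sizes_bp)
    if not window_sizes_bp:
        raise ScanError("empty window-size list")
    pos = gm.positions
    lo, hi = int(pos[0]), int(pos[-1])
    if window_sizes_bp[0] > hi - lo:
        raise ScanError(
            f"smallest window ({window_sizes_bp[0]} bp) exceeds region span ({hi - lo} bp)")
    if step_bp is None:
        step_bp = max(window_sizes_bp[0] // 2, 1)
    rng = np.random.default_rng(seed)

    rows = []
    for w in window_sizes_bp:
        if w > hi - lo:
            continue
        for start in range(lo, hi - w + 1, step_bp):
            end = start + w
            try:
                lcodes_all, lvalid = encode_local_haplotypes(gm, start, "right", k)
                rcodes_all, rvalid = encode_local_haplotypes(gm, end, "left", k)
            except ScanError:
                continue
            lpos = pos[(pos >= start)][:k]
            rpos = pos[(pos <= end)][-k:]
            if len(lpos) < k or len(rpos) < k or lpos[-1] >= rpos[0]:
                continue  # blocks overlap: window too sparse
            both = lvalid & rvalid
            # re-code on the jointly valid chromosomes
            lcodes = _subset_codes(lcodes_all, lvalid, both)
            rcodes = _subset_codes(rcodes_all, rvalid, both)
            n_chrom = int(both.sum())
            try:
                _, _, bic_diff = fit_block_models(
                    lcodes, rcodes, n_restarts=n_restarts, rng=rng)
            except ScanError:
                continue
            rows.append((start, end, w, bic_diff, n_chrom))
    windows = pd.DataFrame(
        rows, columns=["left_bp", "right_bp", "window_size", "bic_diff", "n_chromosomes"])
    return ScanResult(windows=windows, segments=merge_positive_windows(windows))


def _subset_codes(codes, valid_mask, joint_mask):
    """Restrict side codes (defined on valid rows) to jointly valid rows."""
    out = codes[joint_mask[valid_mask]]
    # densify the alphabet again after subsetting
    _, dense = np.unique(out, return_inverse=True)
    return dense


class BlockScanner:
    """Estimator-style wrapper around :func:`scan_region`.

    Parameters
    ----------
    window_sizes_bp : sequence of int
        Candidate segment lengths; mirrors a multi-window-size scan
        (e.g. 0.4–1 Mb on real data).
    step_bp : int, optional
        Window-start step; default half the smallest window.
    k : int
        SNPs per local block (default 2).
    random_state : int, optional
        Seeds the EM restarts.

    Attributes
    ----------
    windows_ : DataFrame of all scored breakpoint pairs.
    segments_ : DataFrame of merged ΔBIC-positive segments.
    """

    def __init__(self, window_sizes_bp=(400_000, 600_000, 800_000, 1_000_000),
                 step_bp=None, k=2, n_restarts=5, random_state=None):
        self.window_sizes_bp = window_sizes_bp
        self.step_bp = step_bp
        self.k = k
        self.n_restarts = n_restarts
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "window_sizes_bp": self.window_sizes_bp, "step_bp": self.step_bp,
            "k": self.k, "n_restarts": self.n_restarts,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, gm: GenotypeMatrix):
        result = scan_region(gm, self.window_sizes_bp, step_bp=self.step_bp,
                             k=self.k, seed=self.random_state,
                             n_restarts=self.n_restarts)
        self.windows_ = result.windows
        self.segments_ = result.segments
        return self
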