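"""Kalman smoothing for the lag-augmented linear DCM.

The discretized observation model stacks L lags of the neural state into an
augmented state z_k = [x_k; x_{k-1}; ...; x_{k-L+1}] in R^{nL}:

    z_{k+1} = F z_k + [w_k; 0; ...],   Cov(w_k) = q I_n
    y_k     = H(h) z_k + e_k,          Cov(e_k) = diag(lambda)

with F the block-companion matrix carrying A_d in its top-left block and
identity shifts below, and H picking each region's own lag stack through its
FIR taps (region i observes only [z_k]_{l n + i}, l = 0..L-1).

The smoother returns the sufficient statistics the EM M-step needs.  All
statistics are expectations under the exact Gaussian posterior; the only
approximation is optional *gain freezing*: once the predicted covariance
stops changing (relative change below ``freeze_tol``) the Riccati recursion
is frozen and the constant gain reused, which leaves the means exact and
perturbs covariances by less than the freeze tolerance.  ``freeze_tol=0``
disables freezing and gives the dense reference smoother.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import InferenceError

__all__ = ["SmootherStats", "smooth_lagged_dcm", "filter_loglik"]


@dataclass
class SmootherStats:
    """Posterior sufficient statistics accumulated over the sequence.

    Transition sums run over the T-1 transitions (pairs k-1 -> k, k=1..T-1);
    observation sums run over all T samples.
    """

    loglik: float
    Sxx: np.ndarray   # sum E[x_{k-1} x_{k-1}^T], transitions
    Cx: np.ndarray    # sum E[x_k x_{k-1}^T], transitions
    Exx2: np.ndarray  # sum E[x_k x_k^T], transitions
    Suu: np.ndarray   # (n, L, L) per-region sum E[u u^T], observations
    suy: np.ndarray   # (n, L) per-region sum y * E[u]
    syy: np.ndarray   # (n,) per-region sum y^2
    T: int


def _apply_F_vec(Ad: np.ndarray, v: np.ndarray, n: int) -> np.ndarray:
    out = np.empty_like(v)
    out[:n] = Ad @ v[:n]
    out[n:] = v[:-n]
    return out


def _apply_F_rows(Ad: np.ndarray, M: np.ndarray, n: int) -> np.ndarray:
    out = np.empty_like(M)
    out[:n] = Ad @ M[:n]
    out[n:] = M[:-n]
    return out


def _FPFt(Ad: np.ndarray, P: np.ndarray, n: int) -> np.ndarray:
    return _apply_F_rows(Ad, _apply_F_rows(Ad, P, n).T, n)


def _obs_project(h: np.ndarray, P: np.ndarray, n: int, L: int) -> np.ndarray:
    """H P for the structured H; returns (n, nL)."""
    P_re = P.reshape(L, n, -1)
    return np.einsum("il,lik->ik", h, P_re)


def _obs_mean(h: np.ndarray, m: np.ndarray, n: int, L: int) -> np.ndarray:
    return np.einsum("il,li->i", h, m.reshape(L, n))


def stationary_augmented_cov(Ad: np.ndarray, q: float, L: int) -> np.ndarray:
    """Stationary covariance of the lag stack for transition matrix Ad.

    Falls back to a diffuse diagonal when Ad is not a contraction.
    """
    n = Ad.shape[0]
    rho = float(np.max(np.abs(np.linalg.eigvals(Ad))))
    if rho >= 0.999:
        scale = q / (1.0 - 0.998**2)
        return scale * np.eye(n * L)
    Sd = linalg.solve_discrete_lyapunov(Ad, q * np.eye(n))
    Sd = (Sd + Sd.T) / 2.0
    P0 = np.empty((n * L, n * L))
    pow_Ad = [np.eye(n)]
    for _ in range(L - 1):
        pow_Ad.append(Ad @ pow_Ad[-1])
    for a in range(L):
        for b in range(a, L):
            blk = pow_Ad[b - a] @ Sd  # E[x_{k-a} x_{k-b}^T]
            P0[a * n:(a + 1) * n, b * n:(b + 1) * n] = blk
            if b > a:
                P0[b * n:(b + 1) * n, a * n:(a + 1) * n] = blk.T
    return (P0 + P0.T) / 2.0


def smooth_lagged_dcm(
    y: np.ndarray,
    Ad: np.ndarray,
    hrfs: np.ndarray,
    lam: np.ndarray,
    q: float,
    P0: np.ndarray,
    freeze_tol: float = 1e-12,
) -> SmootherStats:
    """Run the forward filter and RTS smoother; accumulate EM statistics."""
    T, n = y.shape
    L = hrfs.shape[1]
    nL = n * L
    Qtop = q * np.eye(n)
    R = np.asarray(lam, dtype=float)

    m_pred = np.zeros((T, nL))
    m_filt = np.zeros((T, nL))
    P_pred_hist: list[np.ndarray] = []
    P_filt_hist: list[np.ndarray] = []
    frozen_at = T  # first index with frozen covariances
    Ppc = Pfc = None  # frozen constants
    chol_Sc = None
    HPc = None
    Kc = None
    loglik = 0.0
    log2pi = float(np.log(2.0 * np.pi))

    def _obs_side(P: np.ndarray, k: int):
        HP = _obs_project(hrfs, P, n, L)
        Sk = np.einsum("jl,ilj->ij", hrfs, HP.reshape(n, L, n))
        Sk = (Sk + Sk.T) / 2.0
        Sk[np.diag_indices(n)] += R
        try:
            chol = linalg.cho_factor(Sk, lower=True)
        except linalg.LinAlgError as exc:
            raise InferenceError(
                f"innovation covariance not positive definite at step {k}"
            ) from exc
        K = linalg.cho_solve(chol, HP).T
        return HP, chol, K

    frozen = False
    m = np.zeros(nL)
    P = P0.copy()
    for k in range(T):
        if k > 0:
            m = _apply_F_vec(Ad, m_filt[k - 1], n)
            if not frozen:
                P = _FPFt(Ad, P_filt_hist[-1], n)
                P[:n, :n] += Qtop
                P = (P + P.T) / 2.0
                if (
                    freeze_tol > 0
                    and P_pred_hist
                    and float(np.max(np.abs(P - P_pred_hist[-1])))
                    <= freeze_tol * max(1.0, float(np.max(np.abs(P))))
                ):
                    frozen = True
                    frozen_at = k
                    Ppc = P
        m_pred[k] = m
        if not frozen:
            P_pred_hist.append(P)
            HP, chol, K = _obs_side(P, k)
        elif Kc is None:
            HPc, chol_Sc, Kc = _obs_side(Ppc, k)
            Pfc = Ppc - Kc @ HPc
            Pfc = (Pfc + Pfc.T) / 2.0
            HP, chol, K = HPc, chol_Sc, Kc
        else:
            HP, chol, K = HPc, chol_Sc, Kc
        nu = y[k] - _obs_mean(hrfs, m, n, L)
        alpha = linalg.cho_solve(chol, nu)
        loglik -= 0.5 * (
            n * log2pi
            + 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
            + float(nu @ alpha)
        )
        m = m + K @ nu
        m_filt[k] = m
        if not frozen:
            Pf = P - K @ HP
            Pf = (Pf + Pf.T) / 2.0
            P_filt_hist.append(Pf)
            P = Pf

    def P_filt(k: int) -> np.ndarray:
        return P_filt_hist[k] if k < frozen_at else Pfc

    def P_predicted(k: int) -> np.ndarray:
        return P_pred_hist[k] if k < frozen_at else Ppc

    # ---- backward pass -------------------------------------------------
    m_s = np.zeros((T, nL))
    m_s[T - 1] = m_filt[T - 1]
    Ps = P_filt(T - 1)
    P_sum = Ps.copy()
    Ps0 = None
    J_const = None
    Ps_frozen = False
    Ps_const = None
    # track sums over the transition range (k = 1..T-1) for block stats
    P_sum_trans = np.zeros((2 * n, 2 * n))
    if T >= 2:
        P_sum_trans += Ps[: 2 * n, : 2 * n]

    for k in range(T - 2, -1, -1):
        in_frozen = k >= frozen_at
        if in_frozen and Ps_frozen:
            m_s[k] = m_filt[k] + J_const @ (m_s[k + 1] - m_pred[k + 1])
            P_sum += Ps_const
            if k >= 1:
                P_sum_trans += Ps_const[: 2 * n, : 2 * n]
            if k == 0:
                Ps0 = Ps_const
            continue
        Pf_k = P_filt(k)
        Pp_k1 = P_predicted(k + 1)
        if in_frozen and J_const is not None:
            J = J_const
        else:
            G = _apply_F_rows(Ad, Pf_k, n)  # F P_f
            J = linalg.solve(Pp_k1, G, assume_a="pos").T
            if in_frozen:
                J_const = J
        m_s[k] = m_filt[k] + J @ (m_s[k + 1] - m_pred[k + 1])
        Ps_new = Pf_k + J @ (Ps - Pp_k1) @ J.T
        Ps_new = (Ps_new + Ps_new.T) / 2.0
        if (
            in_frozen
            and freeze_tol > 0
            and float(np.max(np.abs(Ps_new - Ps)))
            <= freeze_tol * max(1.0, float(np.max(np.abs(Ps_new))))
        ):
            Ps_frozen = True
            Ps_const = Ps_new
        Ps = Ps_new
        P_sum += Ps
        if k >= 1:
            P_sum_trans += Ps[: 2 * n, : 2 * n]
        if k == 0:
            Ps0 = Ps

    # ---- accumulate statistics ----------------------------------------
    M = m_s  # (T, nL)
    blk0 = slice(0, n)
    blk1 = slice(n, 2 * n)
    Mt = M[1:]  # rows k = 1..T-1
    Sxx = P_sum_trans[blk1, blk1] + Mt[:, blk1].T @ Mt[:, blk1]
    Cx = P_sum_trans[blk0, blk1] + Mt[:, blk0].T @ Mt[:, blk1]
    Exx2 = P_sum_trans[blk0, blk0] + Mt[:, blk0].T @ Mt[:, blk0]
    Suu = np.empty((n, L, L))
    suy = np.empty((n, L))
    syy = np.einsum("ki,ki->i", y, y)
    for i in range(n):
        ui = np.arange(L) * n + i
        Mu = M[:, ui]
        Suu[i] = P_sum[np.ix_(ui, ui)] + Mu.T @ Mu
        suy[i] = Mu.T @ y[:, i]
    Sxx = (Sxx + Sxx.T) / 2.0
    Exx2 = (Exx2 + Exx2.T) / 2.0
    return SmootherStats(
        loglik=loglik, Sxx=Sxx, Cx=Cx, Exx2=Exx2, Suu=Suu, suy=suy, syy=syy, T=T
    )


def filter_loglik(
    y: np.ndarray,
    Ad: np.ndarray,
    hrfs: np.ndarray,
    lam: np.ndarray,
    q: float,
    P0: np.ndarray,
    freeze_tol: float = 1e-12,
    return_innovations: bool = False,
):
    """Forward filter only: log-likelihood and (optionally) one-step innovations."""
    T, n = y.shape
    L = hrfs.shape[1]
    nL = n * L
    Qtop = q * np.eye(n)
    R = np.asarray(lam, dtype=float)
    m = np.zeros(nL)
    P = P0
    P_prev_pred = None
    frozen = False
    HP = chol = K = None
    loglik = 0.0
    log2pi = float(np.log(2.0 * np.pi))
    innov = np.zeros((T, n)) if return_innovations else None
    for k in range(T):
        if k > 0:
            m = _apply_F_vec(Ad, m, n)
            if not frozen:
                P = _FPFt(Ad, P, n)
                P[:n, :n] += Qtop
                P = (P + P.T) / 2.0
                if (
                    freeze_tol > 0
                    and P_prev_pred is not None
                    and float(np.max(np.abs(P - P_prev_pred)))
                    <= freeze_tol * max(1.0, float(np.max(np.abs(P))))
                ):
                    frozen = True
                P_prev_pred = P
        if not frozen or HP is None:
            HP = _obs_project(hrfs, P, n, L)
            Sk = np.einsum("jl,ilj->ij", hrfs, HP.reshape(n, L, n))
            Sk = (Sk + Sk.T) / 2.0
            Sk[np.diag_indices(n)] += R
            chol = linalg.cho_factor(Sk, lower=True)
            K = linalg.cho_solve(chol, HP).T
        nu = y[k] - _obs_mean(hrfs, m, n, L)
        if return_innovations:
            innov[k] = nu
        alpha = linalg.cho_solve(chol, nu)
        loglik -= 0.5 * (
            n * log2pi
            + 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
            + float(nu @ alpha)
        )
        m = m + K @ nu
        if not frozen:
            P = P - K @ HP
            P = (P + P.T) / 2.0
    if return_innovations:
        return loglik, innov
    return loglik
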