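"""Source/sink profiling from the differential cross-covariance.

Once a model is inferred, directionality lives entirely in the skew-symmetric
S matrix.  The convention throughout the package: ``S[i, j] > 0`` means node
j (the column) acts as the source and node i (the row) as the sink/target, so
a node's *column sum* measures its net tendency to send (> 0) or receive
(< 0).  Summing rows instead flips every sign and the interpretation with it,
leading to the same conclusions.

The time-reversal experiment is the operational check of irreversibility:
fitting the time-flipped recording must flip the sign of every S entry
(entrywise slope near -1, intercept near 0) while leaving zero-lag statistics
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .exceptions import DataError
from .inference import DcmFit, postfit_steady_state
from .model import SteadyState, _check_skew
from .synthetic import BoldRecording, time_reverse

__all__ = [
    "NetworkPartition",
    "HierarchyProfile",
    "ReversalTestResult",
    "inout_node_profile",
    "inout_network_matrix",
    "hierarchy_profile",
    "time_reversal_test",
]


@dataclass
class NetworkPartition:
    """Region -> network assignment with a stable network order."""

    assignment: dict[str, str]
    networks: list[str]

    @classmethod
    def from_assignment(cls, assignment: dict[str, str]) -> "NetworkPartition":
        networks: list[str] = []
        for net in assignment.values():
            if net not in networks:
                networks.append(net)
        if not networks:
            raise DataError("partition assigns no regions")
        return cls(assignment=dict(assignment), networks=networks)


@dataclass
class HierarchyProfile:
    """Node-level in/out profile and the network-pair averaged S matrix."""

    node_inout: np.ndarray
    network_matrix: np.ndarray
    networks: list[str]
    labels: list[str]


@dataclass
class ReversalTestResult:
    """Entrywise comparison of S fitted forward vs on time-reversed data."""

    S: np.ndarray
    S_r: np.ndarray
    slope: float | None
    intercept: float | None
    norm_S: float
    norm_S_r: float
    reversible: bool


def inout_node_profile(S: np.ndarray) -> np.ndarray:
    """Column sums of S: positive = predominantly sender, negative = receiver.

    The profile always sums to zero (skew-symmetry): sending and receiving
    balance across the whole system.
    """
    S = _check_skew(S)
    return S.sum(axis=0)


def inout_network_matrix(
    S: np.ndarray,
    partition: NetworkPartition | dict[str, str],
    labels: list[str],
) -> np.ndarray:
    """Average S over network pairs: M[a, b] = mean of S[i, j], i in a, j in b.

    Row = target network, column = source network; within-network (diagonal)
    averages use off-diagonal S entries only, since diag(S) is structurally
    zero.  The full signed matrix is returned; masking negatives is a display
    choice, not performed here.
    """
    S = _check_skew(S)
    if isinstance(partition, dict):
        partition = NetworkPartition.from_assignment(partition)
    missing = [lab for lab in labels if lab not in partition.assignment]
    if missing:
        raise DataError(f"regions not covered by the partition: {missing}")
    nets = partition.networks
    members = {
        net: np.flatnonzero([partition.assignment[lab] == net for lab in labels])
        for net in nets
    }
    for net, idx in members.items():
        if idx.size == 0:
            raise DataError(f"network '{net}' has no member among these regions")
    K = len(nets)
    M = np.zeros((K, K))
    for a, na in enumerate(nets):
        ia = members[na]
        for b, nb in enumerate(nets):
            jb = members[nb]
            block = S[np.ix_(ia, jb)]
            if a == b:
                if ia.size < 2:
                    M[a, b] = 0.0
                    continue
                mask = ~np.eye(ia.size, dtype=bool)
                M[a, b] = float(block[mask].mean())
            else:
                M[a, b] = float(block.mean())
    return M


def hierarchy_profile(
    S: np.ndarray,
    partition: NetworkPartition | dict[str, str],
    labels: list[str],
) -> HierarchyProfile:
    """Bundle the node in/out profile and the network matrix for one S."""
    if isinstance(partition, dict):
        partition = NetworkPartition.from_assignment(partition)
    return HierarchyProfile(
        node_inout=inout_node_profile(S),
        network_matrix=inout_network_matrix(S, partition, labels),
        networks=list(partition.networks),
        labels=list(labels),
    )


def _extract_S(fit_result) -> np.ndarray:
    if isinstance(fit_result, np.ndarray):
        return fit_result
    if isinstance(fit_result, DcmFit):
        return postfit_steady_state(fit_result).S
    if isinstance(fit_result, SteadyState):
        return fit_result.S
    if isinstance(fit_result, tuple) and len(fit_result) == 2:
        return fit_result[1].S  # (LinearModel, SteadyState)
    raise TypeError(f"cannot extract an S matrix from {type(fit_result)!r}")


def time_reversal_test(
    recording: BoldRecording,
    fit_procedure: Callable[[BoldRecording], object],
    robust: bool = False,
) -> ReversalTestResult:
    """Fit forward and time-reversed recordings and regress S_r on S.

    ``fit_procedure`` maps a recording to anything carrying an S matrix (a
    DcmFit, a SteadyState, a (model, steady-state) pair or S itself).  The
    regression uses strict upper triangles only (skew redundancy removed);
    ``robust=True`` switches to a Theil-Sen fit.  For irreversible dynamics
    the theoretical outcome is slope -1, intercept 0; when the forward S is
    numerically zero the dynamics are reversible and the slope is undefined.
    """
    S = _extract_S(fit_procedure(recording))
    S_r = _extract_S(fit_procedure(time_reverse(recording)))
    iu = np.triu_indices(S.shape[0], k=1)
    x, yv = S[iu], S_r[iu]
    norm_S = float(np.linalg.norm(S, 2))
    norm_S_r = float(np.linalg.norm(S_r, 2))
    scale = float(np.max(np.abs(x))) if x.size else 0.0
    if scale < 1e-12 or float(np.std(x)) < 1e-15:
        return ReversalTestResult(
            S=S, S_r=S_r, slope=None, intercept=None,
            norm_S=norm_S, norm_S_r=norm_S_r, reversible=True,
        )
    if robust:
        res = stats.theilslopes(yv, x)
        slope, intercept = float(res.slope), float(res.intercept)
    else:
        res = stats.linregress(x, yv)
        slope, intercept = float(res.slope), float(res.intercept)
    return ReversalTestResult(
        S=S, S_r=S_r, slope=slope, intercept=intercept,
        norm_S=norm_S, norm_S_r=norm_S_r, reversible=False,
    )
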