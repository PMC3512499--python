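"""HMM smoothing of per-window ancestry labels.

The hidden state is the true ancestral population of a window; the
observation is the SVM's hard label.  Transitions between consecutive
windows follow the expected recombination over the genetic gap ``d``
(Morgans) after ``g`` generations of admixture: each off-diagonal entry is
``(1 - exp(-g d)) / (k' - 1)`` and the diagonal ``exp(-g d)``, the unique
stochastic completion.  Emissions encode the window's cross-validated SVM
success rate ``p``: ``p`` on the diagonal, ``(1 - p)/(k' - 1)`` elsewhere.
Posteriors come from the scaled forward-backward recursion; chains run
independently per chromosome with a uniform initial distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype_io import WindowPartition

__all__ = [
    "AncestryHMM",
    "AncestryCall",
    "build_transition",
    "build_emission",
    "forward_backward",
    "viterbi",
    "decode",
    "smooth_panel",
]


def build_transition(g: float, d: float, k_prime: int) -> np.ndarray:
    """Transition matrix for one inter-window gap of ``d`` Morgans."""
    if k_prime < 2:
        raise ValueError("k' must be at least 2")
    if d < 0:
        raise ValueError("genetic distance d must be non-negative")
    if g <= 0:
        raise ValueError("generations g must be positive")
    stay = np.exp(-g * d)
    off = (1.0 - stay) / (k_prime - 1)
    T = np.full((k_prime, k_prime), off)
    np.fill_diagonal(T, stay)
    return T


def build_emission(p: float, k_prime: int) -> np.ndarray:
    """Emission matrix (state x observed label) for success rate ``p``."""
    if k_prime < 2:
        raise ValueError("k' must be at least 2")
    if not (0.0 < p < 1.0):
        raise ValueError("success rate p must lie strictly in (0, 1)")
    off = (1.0 - p) / (k_prime - 1)
    E = np.full((k_prime, k_prime), off)
    np.fill_diagonal(E, p)
    return E


@dataclass
class AncestryHMM:
    """Chain over one chromosome's windows.

    ``transitions[t]`` links window ``t`` to ``t+1`` (length ``m - 1``);
    ``emissions[t]`` is window ``t``'s emission matrix (length ``m``).
    """

    k_prime: int
    transitions: list[np.ndarray]
    emissions: list[np.ndarray]

    def __post_init__(self) -> None:
        self.pi = np.full(self.k_prime, 1.0 / self.k_prime)

    @classmethod
    def from_parameters(cls, g: float, gaps: list[float],
                        success_rates: list[float], k_prime: int
                        ) -> "AncestryHMM":
        if len(gaps) != len(success_rates) - 1:
            raise ValueError("need one gap fewer than windows")
        return cls(
            k_prime=k_prime,
            transitions=[build_transition(g, d, k_prime) for d in gaps],
            emissions=[build_emission(p, k_prime) for p in success_rates],
        )


def forward_backward(raw_labels: np.ndarray, hmm: AncestryHMM) -> np.ndarray:
    """Exact smoothing posteriors P(state_t | all labels), scaled recursion.

    ``raw_labels`` are 1-based observed labels, one per window of the
    chain.  Per-step normalization keeps the recursion stable for chains of
    tens of thousands of windows.
    """
    obs = np.asarray(raw_labels, dtype=np.int64) - 1
    m = len(obs)
    k = hmm.k_prime
    if obs.min(initial=0) < 0 or obs.max(initial=-1) >= k:
        raise ValueError("observed label out of range 1..k'")
    if len(hmm.emissions) != m or len(hmm.transitions) != m - 1:
        raise ValueError("HMM length does not match label sequence")

    alpha = np.empty((m, k))
    scale = np.empty(m)
    a = hmm.pi * hmm.emissions[0][:, obs[0]]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, m):
        a = (alpha[t - 1] @ hmm.transitions[t - 1]) * hmm.emissions[t][:, obs[t]]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]

    beta = np.empty((m, k))
    beta[m - 1] = 1.0
    for t in range(m - 2, -1, -1):
        b = hmm.transitions[t] @ (hmm.emissions[t + 1][:, obs[t + 1]] * beta[t + 1])
        beta[t] = b / scale[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


def viterbi(raw_labels: np.ndarray, hmm: AncestryHMM) -> np.ndarray:
    """Most probable joint state path (1-based labels); non-default decoder."""
    obs = np.asarray(raw_labels, dtype=np.int64) - 1
    m, k = len(obs), hmm.k_prime
    logpi = np.log(hmm.pi)
    delta = logpi + np.log(hmm.emissions[0][:, obs[0]])
    back = np.zeros((m, k), dtype=np.int64)
    for t in range(1, m):
        cand = delta[:, None] + np.log(hmm.transitions[t - 1])
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + np.log(hmm.emissions[t][:, obs[t]])
    path = np.empty(m, dtype=np.int64)
    path[m - 1] = int(delta.argmax())
    for t in range(m - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path + 1


def _argmax_with_ties(posteriors: np.ndarray) -> np.ndarray:
    """Per-row argmax; exact ties keep the previous decoded label when it is
    among the tied states, else take the lowest index."""
    m, _ = posteriors.shape
    labels = np.empty(m, dtype=np.int64)
    prev = -1
    for t in range(m):
        row = posteriors[t]
        best = row.max()
        tied = np.flatnonzero(row == best)
        if prev - 1 in tied:
            labels[t] = prev
        else:
            labels[t] = int(tied[0]) + 1
        prev = labels[t]
    return labels


@dataclass
class AncestryCall:
    """Smoothed ancestry of one query haplotype across all windows."""

    haplotype_id: str
    posterior: np.ndarray  # (n_windows, k')
    labels: np.ndarray     # 1-based argmax per window
    population_names: list[str] | None = None


def decode(posteriors: np.ndarray, haplotype_id: str = "",
           population_names: list[str] | None = None) -> AncestryCall:
    """Per-window argmax decoding of smoothing posteriors."""
    posteriors = np.asarray(posteriors, dtype=float)
    return AncestryCall(
        haplotype_id=haplotype_id,
        posterior=posteriors,
        labels=_argmax_with_ties(posteriors),
        population_names=population_names,
    )


def smooth_panel(raw: np.ndarray, success_rates: list[float],
                 partition: WindowPartition, g: float, k_prime: int,
                 haplotype_ids: list[str] | None = None,
                 population_names: list[str] | None = None,
                 method: str = "posterior") -> list[AncestryCall]:
    """Smooth raw per-window labels for every haplotype.

    Chains run independently per chromosome (transition structure comes
    from ``partition.gaps``; a ``None`` gap restarts the chain at the
    uniform initial distribution).  ``method`` selects posterior-argmax
    decoding (default) or ``"viterbi"``.
    """
    raw = np.asarray(raw, dtype=np.int64)
    if raw.ndim != 2 or raw.shape[1] != partition.n_windows:
        raise ValueError("raw label matrix does not match partition")
    if len(success_rates) != partition.n_windows:
        raise ValueError("one success rate per window required")
    if method not in ("posterior", "viterbi"):
        raise ValueError(f"unknown decoding method {method!r}")

    chains = partition.chromosome_chains()
    hmms = []
    for chain in chains:
        gaps = [partition.gaps[j] for j in chain[:-1]]
        rates = [success_rates[j] for j in chain]
        hmms.append(AncestryHMM.from_parameters(g, gaps, rates, k_prime))

    ids = haplotype_ids or [f"hap{i}" for i in range(raw.shape[0])]
    calls = []
    for i in range(raw.shape[0]):
        post = np.empty((partition.n_windows, k_prime))
        for chain, hmm in zip(chains, hmms):
            post[chain] = forward_backward(raw[i, chain], hmm)
        if method == "viterbi":
            labels = np.empty(partition.n_windows, dtype=np.int64)
            for chain, hmm in zip(chains, hmms):
                labels[chain] = viterbi(raw[i, chain], hmm)
            calls.append(AncestryCall(ids[i], post, labels, population_names))
        else:
            call = decode(post, ids[i], population_names)
            calls.append(call)
    return calls
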