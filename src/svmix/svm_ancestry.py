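"""Per-window one-against-one linear SVM ancestry classifiers.

Each genomic window gets its own independent ensemble of soft-margin
linear SVMs, one per unordered pair of candidate populations
(k'(k'-1)/2 classifiers for k' populations).  An admixed window is
classified by majority vote of the pairwise classifiers.  Each window's
reliability is summarized by a three-fold cross-validated success rate
``p``, later used as the HMM emission probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .haplotype_io import HaplotypePanel, WindowPartition

__all__ = [
    "P_FLOOR",
    "P_CEIL",
    "BinaryClassifier",
    "WindowClassifierEnsemble",
    "train_binary_svm",
    "cross_validate_window",
    "train_window_ensemble",
    "classify_window",
    "classify_panel",
    "save_ensembles",
    "load_ensembles",
]

# Success rates are clamped away from {0, 1} so no single window can force
# a zero emission probability on the HMM (which would make a confidently
# wrong window impossible to override by its neighbours).
P_FLOOR = 1e-3
P_CEIL = 1.0 - 1e-3


def train_binary_svm(X: np.ndarray, y: np.ndarray, C: float
                     ) -> tuple[np.ndarray, float]:
    """Fit a soft-margin linear SVM; return (weights, bias).

    ``y`` must hold both -1 and +1.  The returned discriminant classifies
    a window as ``sign(w . x + b)``.
    """
    if C <= 0:
        raise ValueError("penalty C must be positive")
    y = np.asarray(y)
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ValueError("both classes must be present")
    clf = SVC(kernel="linear", C=C)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


@dataclass
class BinaryClassifier:
    """Linear discriminant separating population pair (a, b), a < b.

    ``decision(x) = w . x + b``; positive values vote population ``a``.
    """

    pop_a: int
    pop_b: int
    weights: np.ndarray
    bias: float

    def decision(self, x: np.ndarray) -> float:
        return float(self.weights @ x + self.bias)

    def vote(self, x: np.ndarray) -> int:
        return self.pop_a if self.decision(x) > 0 else self.pop_b


@dataclass
class WindowClassifierEnsemble:
    """All pairwise classifiers for one window plus its CV success rate."""

    classifiers: list[BinaryClassifier]
    success_rate: float
    population_names: list[str]
    C: float

    @property
    def k_prime(self) -> int:
        return len(self.population_names)

    @property
    def n_snps(self) -> int:
        return len(self.classifiers[0].weights)


def _train_pairwise(X: np.ndarray, labels: np.ndarray, k: int, C: float
                    ) -> list[BinaryClassifier]:
    out = []
    for a in range(1, k + 1):
        for b in range(a + 1, k + 1):
            mask = (labels == a) | (labels == b)
            y = np.where(labels[mask] == a, 1, -1)
            w, bias = train_binary_svm(X[mask], y, C)
            out.append(BinaryClassifier(a, b, w, bias))
    return out


def _vote(classifiers: list[BinaryClassifier], k: int, x: np.ndarray
          ) -> tuple[np.ndarray, int]:
    """One-vs-one vote; returns (vote counts indexed 0..k-1, winner 1..k).

    Ties in vote count break to the population with the largest summed
    decision margin in its favour across its classifiers, then to the
    lowest population index.
    """
    votes = np.zeros(k, dtype=np.int64)
    margin = np.zeros(k, dtype=float)
    for clf in classifiers:
        dec = clf.decision(x)
        winner = clf.pop_a if dec > 0 else clf.pop_b
        votes[winner - 1] += 1
        margin[clf.pop_a - 1] += dec
        margin[clf.pop_b - 1] -= dec
    best = votes.max()
    tied = np.flatnonzero(votes == best)
    if len(tied) == 1:
        return votes, int(tied[0]) + 1
    tied = tied[margin[tied] == margin[tied].max()]
    return votes, int(tied[0]) + 1


def classify_window(ensemble: WindowClassifierEnsemble, x_window: np.ndarray
                    ) -> tuple[np.ndarray, int]:
    """Classify one window of one haplotype; returns (vote_counts, label)."""
    x = np.asarray(x_window, dtype=float)
    if x.shape[0] != ensemble.n_snps:
        raise ValueError(
            f"window length {x.shape[0]} != classifier length {ensemble.n_snps}")
    return _vote(ensemble.classifiers, ensemble.k_prime, x)


def _fold_assignment(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stratified 3-fold assignment: per population, shuffled round-robin."""
    folds = np.empty(len(labels), dtype=np.int64)
    for pop in np.unique(labels):
        idx = np.flatnonzero(labels == pop)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % 3
    return folds


def cross_validate_window(X_window: np.ndarray, y: np.ndarray, C: float,
                          seed: int) -> float:
    """Three-fold cross-validated success rate for one window.

    Haplotypes are split into three folds stratified by population; for
    each fold the full one-vs-one ensemble is trained on the other two and
    scored on the held-out third.  The mean of the three fold accuracies is
    clamped to ``[P_FLOOR, P_CEIL]``.
    """
    y = np.asarray(y)
    X = np.asarray(X_window, dtype=float)
    pops, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        small = pops[counts.argmin()]
        raise ValueError(
            f"population index {small} has fewer than 3 haplotypes; "
            "3-fold cross-validation impossible")
    k = int(pops.max())
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(y, rng)
    accs = []
    for f in range(3):
        train, test = folds != f, folds == f
        clfs = _train_pairwise(X[train], y[train], k, C)
        pred = np.array([_vote(clfs, k, x)[1] for x in X[test]])
        accs.append(float(np.mean(pred == y[test])))
    return float(np.clip(np.mean(accs), P_FLOOR, P_CEIL))


def train_window_ensemble(panel: HaplotypePanel, partition: WindowPartition,
                          C: float = 1.0, cv_seed: int = 0
                          ) -> list[WindowClassifierEnsemble]:
    """Train an independent one-vs-one ensemble for every window.

    The full ancestral panel trains each window's pairwise classifiers;
    each window's success rate comes from :func:`cross_validate_window`
    with a per-window derived seed so fold splits differ across windows
    but are reproducible.
    """
    if panel.labels is None:
        raise ValueError("ancestral panel must carry population labels")
    pops, counts = np.unique(panel.labels, return_counts=True)
    if counts.min() < 3:
        name = panel.population_names[int(pops[counts.argmin()]) - 1]
        raise ValueError(f"population {name!r} has fewer than 3 haplotypes")
    k = panel.n_populations
    seeds = np.random.SeedSequence(cv_seed).generate_state(partition.n_windows)
    ensembles = []
    for j, win in enumerate(partition.windows):
        Xw = panel.alleles[:, win.start:win.end].astype(float)
        clfs = _train_pairwise(Xw, panel.labels, k, C)
        p = cross_validate_window(Xw, panel.labels, C, int(seeds[j] % (2**31)))
        ensembles.append(WindowClassifierEnsemble(
            classifiers=clfs, success_rate=p,
            population_names=list(panel.population_names), C=C))
    return ensembles


def classify_panel(ensembles: list[WindowClassifierEnsemble],
                   query: HaplotypePanel, partition: WindowPartition
                   ) -> np.ndarray:
    """Raw per-window labels (haplotypes x windows), no smoothing.

    The query's SNP columns must match the partition's panel exactly (same
    ids in the same order); total window span must equal query columns.
    """
    if len(ensembles) != partition.n_windows:
        raise ValueError("one ensemble per window required")
    total = partition.windows[-1].end if partition.windows else 0
    if query.n_snps != total:
        raise ValueError(
            f"query has {query.n_snps} SNPs but partition spans {total}")
    raw = np.empty((query.n_haplotypes, partition.n_windows), dtype=np.int64)
    for j, (win, ens) in enumerate(zip(partition.windows, ensembles)):
        block = query.alleles[:, win.start:win.end].astype(float)
        for i in range(query.n_haplotypes):
            raw[i, j] = _vote(ens.classifiers, ens.k_prime, block[i])[1]
    return raw


def check_alignment(train_panel: HaplotypePanel, query: HaplotypePanel) -> None:
    """Raise if the query's SNP columns do not match the training panel."""
    if train_panel.n_snps != query.n_snps:
        raise ValueError("panels have different SNP counts")
    mism = np.flatnonzero(train_panel.snp_ids != query.snp_ids)
    if mism.size:
        j = int(mism[0])
        raise ValueError(
            f"SNP mismatch at column {j}: {train_panel.snp_ids[j]!r} vs "
            f"{query.snp_ids[j]!r}")


# ---------------------------------------------------------------------------
# Serialization

_FORMAT_VERSION = 1


def save_ensembles(ensembles: list[WindowClassifierEnsemble],
                   path: str | Path, window_size: int | None = None) -> None:
    """Serialize trained ensembles to a versioned JSON container."""
    doc = {
        "format_version": _FORMAT_VERSION,
        "window_size": window_size,
        "population_names": ensembles[0].population_names if ensembles else [],
        "C": ensembles[0].C if ensembles else None,
        "windows": [
            {
                "success_rate": e.success_rate,
                "classifiers": [
                    {"pop_a": c.pop_a, "pop_b": c.pop_b, "bias": c.bias,
                     "weights": c.weights.tolist()}
                    for c in e.classifiers
                ],
            }
            for e in ensembles
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_ensembles(path: str | Path) -> list[WindowClassifierEnsemble]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported ensemble file version: "
                         f"{doc.get('format_version')}")
    out = []
    for wdoc in doc["windows"]:
        clfs = [BinaryClassifier(c["pop_a"], c["pop_b"],
                                 np.asarray(c["weights"], dtype=float),
                                 float(c["bias"]))
                for c in wdoc["classifiers"]]
        out.append(WindowClassifierEnsemble(
            classifiers=clfs, success_rate=float(wdoc["success_rate"]),
            population_names=list(doc["population_names"]), C=float(doc["C"])))
    return out
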