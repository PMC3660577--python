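"""Benchmark statistics over model ensembles.

The central quantity is %sA, the percentage of trajectory-endpoint models
whose segment backbone RMSD to the native is below 1 Angstrom (strict
inequality).  A case is "sampled" if any model is sub-Angstrom and
"identified" if the lowest-scoring model is; the rank is the 1-based
position of the best-scoring sub-Angstrom model in score order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBANGSTROM = 1.0  # Angstrom


@dataclass
class CaseResult:
    """Per-model (score, rmsd) pairs for one benchmark case."""

    case_id: str
    scores: np.ndarray
    rmsds: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.rmsds = np.asarray(self.rmsds, dtype=float)
        if self.scores.shape != self.rmsds.shape or self.scores.ndim != 1:
            raise ValueError("scores and rmsds must be matching 1-D arrays")
        if self.n_models < 1:
            raise ValueError("a case needs at least one model")
        if np.any(self.rmsds < 0):
            raise ValueError("negative RMSD")

    @property
    def n_models(self) -> int:
        return len(self.scores)


def percent_subangstrom(case: CaseResult,
                        threshold: float = SUBANGSTROM) -> float:
    """100 x fraction of models with RMSD strictly below the threshold."""
    return 100.0 * float(np.count_nonzero(case.rmsds < threshold)) \
        / case.n_models


def classify_case(case: CaseResult) -> dict:
    """Sampled / identified flags and the rank of the best-scoring
    sub-Angstrom model (1-based, score order, ties broken by model order);
    rank is None when nothing sub-Angstrom was sampled."""
    sub = case.rmsds < SUBANGSTROM
    sampled = bool(np.any(sub))
    order = np.argsort(case.scores, kind="stable")
    identified = sampled and bool(sub[order[0]])
    rank = None
    if sampled:
        rank = 1 + int(np.nonzero(sub[order])[0][0])
    return {"sampled": sampled, "identified": identified, "rank": rank}


def median_psa(cases, repeats=None) -> dict:
    """Median per-case %sA; with ``repeats`` (a list of case lists from
    independent simulations), the mean and standard deviation of that
    median across repeats."""
    if repeats is None:
        repeats = [cases]
        medians = [float(np.median([percent_subangstrom(c) for c in cases]))]
    else:
        medians = [float(np.median([percent_subangstrom(c) for c in rep]))
                   for rep in repeats]
    return {"median_psa": float(np.mean(medians)),
            "sd": float(np.std(medians, ddof=0)),
            "per_repeat": medians}


def expected_additive_psa(individual, baseline) -> tuple:
    """Expected median %sA if improvements combined additively.

    ``individual``: iterable of (mean, sd) per strategy; ``baseline``:
    (mean, sd) of the unmodified protocol.  The expectation adds each
    strategy's contribution over the baseline to the baseline; the spread is
    the sum of all standard deviations (baseline included).
    """
    base_mean, base_sd = baseline
    expected = base_mean + sum(m - base_mean for m, _ in individual)
    spread = base_sd + sum(sd for _, sd in individual)
    return expected, spread


def cluster_models(rmsd_matrix: np.ndarray, radius: float = 1.0) -> np.ndarray:
    """Greedy center-based clustering on a pairwise segment-RMSD matrix.

    Repeatedly takes the unassigned model with the most unassigned
    neighbours within ``radius`` (ties broken by lowest index) as a cluster
    center and assigns its neighbourhood to it.  Returns an integer cluster
    label per model; labels are ordered by decreasing cluster size (ties by
    center index).
    """
    D = np.asarray(rmsd_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("rmsd_matrix must be square")
    unassigned = np.ones(n, dtype=bool)
    groups = []
    while unassigned.any():
        within = (D <= radius) & unassigned[None, :]
        counts = np.where(unassigned, within.sum(axis=1), -1)
        center = int(np.argmax(counts))
        members = np.nonzero(within[center] & unassigned)[0]
        groups.append((len(members), center, members))
        unassigned[members] = False
    groups.sort(key=lambda g: (-g[0], g[1]))
    labels = np.empty(n, dtype=int)
    for lab, (_, _, members) in enumerate(groups):
        labels[members] = lab
    return labels


def case_from_table(path, case_id: str | None = None) -> CaseResult:
    """Load a CaseResult from a protocol score table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    if "failed" in df.columns:
        df = df[~df["failed"].astype(bool)]
    return CaseResult(case_id=case_id or str(path),
                      scores=df["score"].to_numpy(),
                      rmsds=df["rmsd"].to_numpy())


def summarize_cases(cases) -> pd.DataFrame:
    """Per-case %sA, sampled/identified and rank as a tidy table."""
    rows = []
    for c in cases:
        info = classify_case(c)
        rows.append({"case_id": c.case_id, "n_models": c.n_models,
                     "percent_subangstrom": percent_subangstrom(c), **info})
    return pd.DataFrame(rows)
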