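"""Exhaustive feature-subset experiment and feature-significance tables.

Every non-empty subset of the ten texture features is written as a 10-bit
code ``No`` in 1..1023 (bit i−1 set ⇔ feature w(i) included); code 64 is
{w7}, code 524 is {w3, w4, w10}.  One sweep fits, for every code, a full
CART tree and its 1-SE-pruned counterpart on a fresh random
learn/valid/test split — 2 trees per code, the 2·2^10 accounting — and
evaluates both on the test split.  The "optimal" subset of a sweep
minimises the pruned-tree classification error, with ties broken by fewer
terminal nodes and then by lower code (the Pareto-front reading of
error-versus-size scatter).

Because the splits are random, the whole sweep is repeated R times and the
identity of the optimal subset is tallied: how often each feature appears
in the winning subset (normalised to 100 %), how often each feature occurs
among the disqualified configurations, how often feature *pairs* co-occur
among disqualified configurations, and a histogram of winning codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cart import (
    ConfusionCounts,
    evaluate,
    fit_cart,
    metrics,
    prune_one_se,
    split_equal_thirds,
)

N_FEATURES = 10
N_CODES = (1 << N_FEATURES) - 1  # 1023 non-empty subsets


class CodeError(ValueError):
    """Subset code outside 1..1023 or empty membership."""


def decode_subset(code: int) -> np.ndarray:
    """Boolean membership vector of a subset code (bit i−1 ⇔ w(i))."""
    code = int(code)
    if not 1 <= code <= N_CODES:
        raise CodeError(f"subset code must be in 1..{N_CODES}, got {code}")
    return ((code >> np.arange(N_FEATURES)) & 1).astype(bool)


def encode_subset(membership) -> int:
    """Inverse of :func:`decode_subset`; rejects the empty subset."""
    m = np.asarray(membership).astype(bool)
    if m.shape != (N_FEATURES,):
        raise CodeError(f"membership must have length {N_FEATURES}")
    if not m.any():
        raise CodeError("the empty feature subset has no code")
    return int((m << np.arange(N_FEATURES)).sum())


@dataclass
class SweepRecord:
    """Full- and pruned-tree results for one subset code."""

    code: int
    membership: tuple
    full: ConfusionCounts
    full_leaves: int
    pruned: ConfusionCounts
    pruned_leaves: int

    @property
    def full_error_pct(self) -> float:
        return metrics(self.full)["error_pct"]

    @property
    def pruned_error_pct(self) -> float:
        return metrics(self.pruned)["error_pct"]


def run_sweep(X, y, seed: int, prune: str = "validation", folds: int = 10) -> list:
    """Fit a full and a pruned tree for every subset code 1..1023.

    One random stratified learn/valid/test split is drawn per sweep (seeded);
    for each code the feature matrix is restricted to the member columns,
    a full tree is grown on the learning split, pruned by the 1-SE rule
    (against the validation split by default, or by cross-validation with
    ``prune="cv"``), and both trees are evaluated on the test split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    data = split_equal_thirds(X, y, seed)
    Xl, yl = data.learning
    Xv, yv = data.validation
    Xt, yt = data.test
    records = []
    for code in range(1, N_CODES + 1):
        member = decode_subset(code)
        Xl_s, Xv_s, Xt_s = Xl[:, member], Xv[:, member], Xt[:, member]
        full = fit_cart(Xl_s, yl)
        if prune == "validation":
            pruned = prune_one_se(full, Xl_s, yl, method="validation", validation=(Xv_s, yv))
        else:
            pruned = prune_one_se(full, Xl_s, yl, method=prune, folds=folds, seed=seed)
        records.append(
            SweepRecord(
                code=code,
                membership=tuple(bool(b) for b in member),
                full=evaluate(full, Xt_s, yt),
                full_leaves=full.n_leaves,
                pruned=evaluate(pruned, Xt_s, yt),
                pruned_leaves=pruned.n_leaves,
            )
        )
    return records


def sweep_table(records):
    """Sweep results as a DataFrame (code, membership flags, both trees)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"No": r.code}
        row.update({f"w{i + 1}": int(b) for i, b in enumerate(r.membership)})
        for tag, c, leaves in (("typical", r.full, r.full_leaves), ("cut", r.pruned, r.pruned_leaves)):
            m = metrics(c)
            row.update(
                {
                    f"{tag}_TP": c.tp,
                    f"{tag}_FN": c.fn,
                    f"{tag}_TN": c.tn,
                    f"{tag}_FP": c.fp,
                    f"{tag}_node": leaves,
                    f"{tag}_ACC_pct": 100.0 * m["ACC"],
                    f"{tag}_FNFP_pct": m["error_pct"],
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def pareto_front(records) -> list:
    """Records not dominated in (pruned error %, pruned terminal nodes)."""
    front = []
    for r in records:
        dominated = any(
            (s.pruned_error_pct <= r.pruned_error_pct and s.pruned_leaves <= r.pruned_leaves)
            and (s.pruned_error_pct < r.pruned_error_pct or s.pruned_leaves < r.pruned_leaves)
            for s in records
        )
        if not dominated:
            front.append(r)
    return front


def select_optimal(records) -> int:
    """Code of the optimal subset of one sweep.

    Minimum pruned-tree error; ties broken by fewer terminal nodes, then by
    lower code.  (The winner is by construction a member of the Pareto
    front over error and size.)
    """
    if not records:
        raise ValueError("no sweep records")
    best = min(records, key=lambda r: (r.pruned_error_pct, r.pruned_leaves, r.code))
    return best.code


@dataclass
class SignificanceTables:
    """Feature-frequency summaries over repeated sweeps.

    ``optimal_freq``/``disqualified_freq`` are per-feature percentages
    normalised to sum to 100; ``pair_freq[i, j]`` is the percentage of
    disqualified configurations containing both w(i+1) and w(j+1) (the
    diagonal holds single-feature percentages); ``code_counts[code]``
    counts how often each code won a repetition.
    """

    optimal_freq: np.ndarray
    disqualified_freq: np.ndarray
    pair_freq: np.ndarray
    code_counts: np.ndarray
    repetitions: int

    def optimal_frame(self):
        import pandas as pd

        return pd.Series(self.optimal_freq, index=[f"w{i}" for i in range(1, 11)])

    def disqualified_frame(self):
        import pandas as pd

        return pd.Series(self.disqualified_freq, index=[f"w{i}" for i in range(1, 11)])


def significance(X, y, repetitions: int = 50, seed: int = 0, prune: str = "validation") -> SignificanceTables:
    """Repeat the subset sweep and tally feature significance.

    Each repetition draws a fresh random split (child seeds derived from the
    master seed), runs the full 1023-code sweep, and selects the optimal
    subset.  Tallied over repetitions:

    * how often each feature is a member of the optimal subset,
    * how often each feature occurs among the 1022 disqualified
      configurations of a repetition,
    * how often feature pairs co-occur among disqualified configurations,
    * the histogram of winning codes.

    The per-feature tables are normalised to sum to 100 %.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=repetitions)

    all_codes = np.arange(1, N_CODES + 1)
    member_matrix = ((all_codes[:, None] >> np.arange(N_FEATURES)) & 1).astype(bool)
    total_feature = member_matrix.sum(axis=0).astype(float)  # 512 each
    total_pairs = (member_matrix.astype(float).T @ member_matrix.astype(float))

    opt_counts = np.zeros(N_FEATURES)
    disq_counts = np.zeros(N_FEATURES)
    pair_counts = np.zeros((N_FEATURES, N_FEATURES))
    code_counts = np.zeros(N_CODES + 1, dtype=int)
    for s in rep_seeds:
        records = run_sweep(X, y, int(s), prune=prune)
        code = select_optimal(records)
        m = decode_subset(code).astype(float)
        opt_counts += m
        disq_counts += total_feature - m
        pair_counts += total_pairs - np.outer(m, m)
        code_counts[code] += 1

    n_disq = repetitions * (N_CODES - 1)
    return SignificanceTables(
        optimal_freq=100.0 * opt_counts / opt_counts.sum(),
        disqualified_freq=100.0 * disq_counts / disq_counts.sum(),
        pair_freq=100.0 * pair_counts / n_disq,
        code_counts=code_counts,
        repetitions=repetitions,
    )
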