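"""Independent naive reimplementation of the transform, used only as a test oracle.

Everything here is written with explicit Python loops and numpy's eigensolver
(the package uses scipy's), so agreement with the package is a genuine
cross-check of the pipeline's structure, not a tautology.
"""

import numpy as np


def naive_embed(z, l):
    z = list(map(float, z))
    k = len(z)
    return np.array([[z[r + q] for q in range(l)] for r in range(k - l + 1)])


def naive_gram(A):
    n, l = A.shape
    S = np.zeros((l, l))
    for a in range(l):
        for b in range(l):
            acc = 0.0
            for r in range(n):
                acc += A[r, a] * A[r, b]
            S[a, b] = acc
    return (S + S.T) / 2.0


def naive_law(S):
    vals, vecs = np.linalg.eigh(S)  # ascending
    v = vecs[:, 0].copy()
    pivot = int(np.flatnonzero(np.abs(v) == np.abs(v).max())[0])
    if v[pivot] < 0:
        v = -v
    return v / np.linalg.norm(v), max(float(vals[0]), 0.0)


def naive_sample_var(x):
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    return float(((x - mu) ** 2).sum() / (x.shape[0] - 1))


def naive_transform(train_series, train_labels, test_series, l, absolute_mean=True):
    """Full pipeline with loops: returns (means, variances) arrays.

    ``train_series[i][j]`` / ``test_series[i][j]`` are 1-D arrays; labels are
    1-based ints.  Output rows are test instances, columns ordered
    channel-major then class.
    """
    tau = len(train_series)
    m = len(train_series[0])
    c = max(train_labels)
    banks = []
    for j in range(m):
        V = np.zeros((l, tau))
        for i in range(tau):
            v, _ = naive_law(naive_gram(naive_embed(train_series[i][j], l)))
            V[:, i] = v
        banks.append(V)
    means, variances = [], []
    for te in range(len(test_series)):
        row_m, row_v = [], []
        for j in range(m):
            S = naive_gram(naive_embed(test_series[te][j], l))
            P = S @ banks[j]
            for cls in range(1, c + 1):
                cols = [i for i in range(tau) if train_labels[i] == cls]
                variances_per_col = [naive_sample_var(P[:, i]) for i in cols]
                best = cols[int(np.argmin(variances_per_col))]
                o = P[:, best]
                mu = float(o.mean())
                row_m.append(abs(mu) if absolute_mean else mu)
                row_v.append(naive_sample_var(o))
        means.append(row_m)
        variances.append(row_v)
    return np.array(means), np.array(variances)
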