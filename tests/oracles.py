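"""Independent brute-force oracles used to check the analytical code paths.

These deliberately avoid the package's log-sum-exp / inclusion-exclusion
machinery: hypothesis evidences are accumulated by explicit enumeration of
causal-variant configurations, with per-hypothesis max-scaling to stay in
float range.
"""

import itertools
import math

import numpy as np


def wakefield_log_abf(beta, se, prior_sd):
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * math.log(v / (v + w)) + z2 * w / (2 * (v + w))


def enumerate_pairwise(lab1, lab2, p1, p2, p12):
    """Posterior over H0..H4 by enumerating single-causal-variant
    configurations for each hypothesis directly."""
    lab1 = np.asarray(lab1)
    lab2 = np.asarray(lab2)
    m = lab1.size
    m1, m2 = lab1.max(), lab2.max()
    b1 = np.exp(lab1 - m1)
    b2 = np.exp(lab2 - m2)

    logw = [0.0]
    logw.append(math.log(p1) + m1 + math.log(math.fsum(b1)))
    logw.append(math.log(p2) + m2 + math.log(math.fsum(b2)))
    s3 = math.fsum(
        b1[j] * b2[k] for j in range(m) for k in range(m) if j != k
    )
    logw.append(math.log(p1) + math.log(p2) + m1 + m2 + math.log(s3))
    s4 = math.fsum(b1[j] * b2[j] for j in range(m))
    logw.append(math.log(p12) + m1 + m2 + math.log(s4))

    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def enumerate_moloc(labs, priors, configs):
    """Configuration posteriors for three traits by explicit enumeration of
    distinct-variant assignments to each configuration's trait groups."""
    labs = [np.asarray(a) for a in labs]
    m = labs[0].size
    ms = [a.max() for a in labs]
    bfs = [np.exp(a - mx) for a, mx in zip(labs, ms)]

    logw = {}
    for name, groups in configs:
        if not groups:
            logw[name] = 0.0
            continue
        scale = sum(ms[t] for g in groups for t in g)
        prior = sum(math.log(priors[len(g) - 1]) for g in groups)
        terms = []
        for assign in itertools.permutations(range(m), len(groups)):
            prod = 1.0
            for g, j in zip(groups, assign):
                for t in g:
                    prod *= bfs[t][j]
            terms.append(prod)
        # groups are distinguishable by trait membership, so each ordered
        # assignment of distinct variants counts exactly once
        total = math.fsum(terms)
        logw[name] = (
            prior + scale + math.log(total) if total > 0 else -math.inf
        )
    names = list(logw)
    arr = np.array([logw[n] for n in names])
    w = np.exp(arr - arr.max())
    w /= w.sum()
    return dict(zip(names, w))


def stepup_bh(pvalues):
    """Textbook Benjamini-Hochberg step-up, by definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q
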