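"""Brute-force single-sample enrichment oracle, written independently of
the package implementation (pure python loops, no numpy vectorization).
Used only to cross-check the fast engine on small instances."""

from math import erf, sqrt


def phi(x: float) -> float:
    return 0.5 * (1.0 + erf(x / sqrt(2.0)))


def naive_kcdf(x):
    """x: list of rows (genes) of equal-length lists (samples)."""
    p, n = len(x), len(x[0])
    z = [[0.0] * n for _ in range(p)]
    for i in range(p):
        row = x[i]
        mean = sum(row) / n
        var = sum((v - mean) ** 2 for v in row) / (n - 1)
        sd = sqrt(var)
        if sd == 0.0:
            for j in range(n):
                z[i][j] = 0.5
            continue
        h = sd / 4.0
        for j in range(n):
            z[i][j] = sum(phi((row[j] - row[k]) / h) for k in range(n)) / n
    return z


def naive_sample_order(z, j):
    """Gene indices ranked by decreasing z in sample j, stable on ties."""
    return sorted(range(len(z)), key=lambda g: (-z[g][j], g))


def naive_walk(z, j, geneset, tau=1.0):
    """Step-by-step weighted random walk for one sample and one gene set."""
    p = len(z)
    order = naive_sample_order(z, j)
    m = len(geneset)
    r_by_pos = [abs(p / 2.0 - (k + 1)) for k in range(p)]
    denom = sum(
        r_by_pos[k] ** tau for k, g in enumerate(order) if g in geneset
    )
    nu = 0.0
    vmax = 0.0
    vmin = 0.0
    for k, g in enumerate(order):
        if g in geneset:
            nu += r_by_pos[k] ** tau / denom
        else:
            nu -= 1.0 / (p - m)
        vmax = max(vmax, nu)
        vmin = min(vmin, nu)
    return vmax + vmin


def naive_es_matrix(x, genesets, tau=1.0):
    """Full scores: dict of signature name -> list of per-sample ES."""
    z = naive_kcdf(x)
    n = len(x[0])
    return {
        name: [naive_walk(z, j, set(gs), tau) for j in range(n)]
        for name, gs in genesets.items()
    }
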