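"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: surface areas
come from dense quadrature of the parametric area integral, statistics from
textbook formulas evaluated directly.
"""

import numpy as np
from scipy.integrate import simpson


def bumpy_sphere_area_quadrature(R, a, k, n=1501):
    """Area of r(theta, phi) = R(1 + a sin(k theta) sin(k phi)) by Simpson
    quadrature of  dA = r sqrt(r_phi^2 + sin^2(theta) (r_theta^2 + r^2))."""
    theta = np.linspace(0.0, np.pi, n)
    phi = np.linspace(-np.pi, np.pi, n)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    r = R * (1.0 + a * np.sin(k * T) * np.sin(k * P))
    r_t = R * a * k * np.cos(k * T) * np.sin(k * P)
    r_p = R * a * k * np.sin(k * T) * np.cos(k * P)
    integrand = r * np.sqrt(r_p**2 + np.sin(T) ** 2 * (r_t**2 + r**2))
    return simpson(simpson(integrand, x=phi, axis=1), x=theta)


def welch_t_oracle(a, b):
    """Welch statistic, Welch-Satterthwaite df, two-sided p, by the formulas."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def pooled_t_oracle(a, b):
    """Pooled-variance two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def pearson_oracle(x, y):
    """Pearson r and two-sided p via the t transform, from first principles."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, 2.0 * tdist.sf(abs(t), n - 2)


def spearman_oracle(x, y):
    """Plain Spearman rho as Pearson on mid-ranks."""
    from scipy.stats import rankdata

    return pearson_oracle(rankdata(x), rankdata(y))[0]


def bh_oracle(p):
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj
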