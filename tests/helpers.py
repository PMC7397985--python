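"""Shared test utilities: independent oracles and pedigree builders.

Everything here is deliberately independent of the implementation paths it
checks: gene dropping estimates relatedness by forward allele simulation,
the REML oracle maximizes the restricted likelihood directly, and the
half-sib estimator is a moment (ANOVA) calculation.
"""

from __future__ import annotations

import numpy as np

from epoherit.pedigree import Pedigree


def random_pedigree(rng: np.random.Generator, n_target: int = 30,
                    n_generations: int = 4) -> Pedigree:
    """Random multi-generation pedigree with missing parents and both sexes."""
    per_gen = max(2, n_target // n_generations)
    records = []
    sex = {}
    females: list[str] = []
    males: list[str] = []
    count = 0
    for g in range(n_generations):
        new_f, new_m = [], []
        for _ in range(per_gen):
            count += 1
            name = f"g{g}i{count}"
            if g == 0 or not females or not males or rng.random() < 0.2:
                dam = sire = None
            else:
                dam = str(rng.choice(females))
                sire = str(rng.choice(males))
                if rng.random() < 0.15:
                    dam = None
                elif rng.random() < 0.15:
                    sire = None
            records.append((name, dam, sire))
            if rng.random() < 0.5:
                sex[name] = "F"
                new_f.append(name)
            else:
                sex[name] = "M"
                new_m.append(name)
        females, males = new_f or females, new_m or males
    return Pedigree.from_records(records, sex=sex)


def gene_drop_relatedness(
    ped: Pedigree, n_drops: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Monte-Carlo numerator relationships by gene dropping.

    Two uniquely labelled alleles per founder are dropped down the pedigree
    with Mendelian transmission.  The pairwise statistic per drop is half the
    number of identical-by-descent allele matches among the four cross pairs
    (equal to twice the realized kinship); the diagonal uses 1 + IBD of the
    individual's own two alleles.  Returns (A_hat, SE, id order).
    """
    order = ped.order
    n = len(order)
    pos = {v: k for k, v in enumerate(order)}
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    next_label = 0
    take = np.arange(n_drops)
    for i, name in enumerate(order):
        for slot, p in enumerate(ped.parents(name)):
            if p is None:
                alleles[i, slot] = next_label
                next_label += 1
            else:
                pi = pos[p]
                which = rng.integers(0, 2, n_drops)
                alleles[i, slot] = alleles[pi, which, take]

    A_hat = np.empty((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        self_ibd = (alleles[i, 0] == alleles[i, 1]).astype(np.float64)
        A_hat[i, i] = 1.0 + self_ibd.mean()
        se[i, i] = self_ibd.std(ddof=1) / np.sqrt(n_drops) if n_drops > 1 else 0.0
        if i + 1 < n:
            # stat per drop: 0.5 * number of IBD matches among 2x2 allele pairs
            eq = (alleles[i, None, :, None, :] == alleles[i + 1:, None, :, :])
            stat = 0.5 * eq.sum(axis=(1, 2))
            A_hat[i, i + 1:] = A_hat[i + 1:, i] = stat.mean(axis=1)
            s = stat.std(axis=1, ddof=1) / np.sqrt(n_drops)
            se[i, i + 1:] = se[i + 1:, i] = s
    return A_hat, se, order


def reml_intercept_animal(y: np.ndarray, A_phen: np.ndarray) -> tuple[float, float]:
    """Direct REML maximizer for the intercept-only Gaussian animal model.

    Works in the eigenbasis of the phenotyped-submatrix relationship matrix;
    independent of the MCMC code path.
    """
    from scipy import optimize

    n = len(y)
    w, V = np.linalg.eigh(A_phen)
    yt = V.T @ y
    ot = V.T @ np.ones(n)

    def neg_restricted_ll(params):
        sa, se = np.exp(params)
        d = sa * w + se
        winv_o = ot / d
        mu = (winv_o @ yt) / (winv_o @ ot)
        r = yt - mu * ot
        return 0.5 * (np.sum(np.log(d)) + np.sum(r * r / d)
                      + np.log(np.sum(ot * ot / d)))

    res = optimize.minimize(neg_restricted_ll, [np.log(0.5), np.log(0.5)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8})
    sa, se = np.exp(res.x)
    return float(sa), float(se)


def half_sib_h2_anova(trait: np.ndarray, sire_of: np.ndarray) -> float:
    """Paternal half-sib moment estimator: h2 = 4 * sigma2_sire / sigma2_P."""
    sires = np.unique(sire_of)
    s = len(sires)
    k = len(trait) / s  # balanced design
    group_means = np.array([trait[sire_of == x].mean() for x in sires])
    grand = trait.mean()
    msb = k * np.sum((group_means - grand) ** 2) / (s - 1)
    ssw = sum(np.sum((trait[sire_of == x] - gm) ** 2)
              for x, gm in zip(sires, group_means))
    msw = ssw / (len(trait) - s)
    sigma2_s = max((msb - msw) / k, 0.0)
    return 4.0 * sigma2_s / (sigma2_s + msw)


def lognormal_poisson_mc(
    mu: float, sigma2_A: float, sigma2_rest: float, n_draws: int,
    rng: np.random.Generator, n_batches: int = 100,
) -> dict[str, tuple[float, float]]:
    """Simulation oracle for data-scale parameters of the lognormal-Poisson
    model, with breeding-value decomposition.

    Returns {quantity: (estimate, SE)} for mean_obs, var_obs, sigma2_A_obs
    and h2_obs.  sigma2_A_obs is estimated as cov(y, b)^2 / sigma2_A, an
    identity of the psi = E[exp(eta)] linearization that does not reuse the
    closed forms.  SEs come from batch means.
    """
    per = n_draws // n_batches
    stats = np.empty((n_batches, 4))
    for b in range(n_batches):
        bv = rng.normal(0.0, np.sqrt(sigma2_A), per) if sigma2_A > 0 else np.zeros(per)
        rest = rng.normal(0.0, np.sqrt(sigma2_rest), per) if sigma2_rest > 0 \
            else np.zeros(per)
        y = rng.poisson(np.exp(mu + bv + rest)).astype(np.float64)
        m = y.mean()
        v = y.var()
        if sigma2_A > 0:
            cov_yb = np.mean(y * bv) - m * bv.mean()
            s2a_obs = cov_yb**2 / sigma2_A
        else:
            s2a_obs = 0.0
        stats[b] = (m, v, s2a_obs, s2a_obs / v if v > 0 else 0.0)
    est = stats.mean(axis=0)
    se = stats.std(axis=0, ddof=1) / np.sqrt(n_batches)
    names = ["mean_obs", "var_obs", "sigma2_A_obs", "h2_obs"]
    return {nm: (float(e), float(s)) for nm, e, s in zip(names, est, se)}
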