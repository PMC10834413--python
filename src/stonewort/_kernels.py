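"""Numba kernels for the Polya-Gamma NNGP occupancy sampler.

Everything here operates on plain arrays; index bookkeeping (NNGP ordering,
CSR maps from points to point-year rows, dependents of each spatial
location) is prepared in :mod:`stonewort.model`.

The Polya-Gamma PG(1, z) sampler is Devroye's exact alternating-series
rejection method (PG(1, z) = J*(1, z/2) / 4), so the conjugate updates for
the logit-linear coefficients are exact Gibbs steps.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series crossover point for J*(1, z)
_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Polya-Gamma PG(1, z)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pnorm(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _mass_texpon(z):
    """Probability that the proposal draws from the (truncated) exponential part."""
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + math.log(_pnorm(b))
    xa = x0 + z + math.log(_pnorm(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(rng, z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC)."""
    t = _TRUNC
    x = t + 1.0
    if 1.0 / t > z:  # mu > t: rejection from truncated inverse-chi-square
        alpha = 0.0
        while rng.random() > alpha:
            e1 = rng.exponential()
            e2 = rng.exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = rng.exponential()
                e2 = rng.exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = rng.standard_normal()
            y = y * y
            mu_y = mu * y
            x = mu + 0.5 * mu * mu_y - 0.5 * mu * math.sqrt(4.0 * mu_y + mu_y * mu_y)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _a_coef(n, x):
    """Terms of the alternating series for the J*(1, z) density."""
    np5 = n + 0.5
    if x > _TRUNC:
        return math.pi * np5 * math.exp(-0.5 * np5 * np5 * math.pi * math.pi * x)
    return (
        math.pi
        * np5
        * math.pow(2.0 / (math.pi * x), 1.5)
        * math.exp(-2.0 * np5 * np5 / x)
    )


@njit(cache=True)
def pg_draw(rng, psi):
    """One draw from PG(1, psi)."""
    z = 0.5 * abs(psi)
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    while True:
        if rng.random() < _mass_texpon(z):
            x = _TRUNC + rng.exponential() / fz
        else:
            x = _rtigauss(rng, z)
        s = _a_coef(0, x)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def pg_draw_vec(rng, psi, out):
    for i in range(psi.shape[0]):
        out[i] = pg_draw(rng, psi[i])


# ---------------------------------------------------------------------------
# NNGP factors and log density
# ---------------------------------------------------------------------------

@njit(cache=True)
def nngp_unit_factors(nbr, n_nbr, dist_nn, dist_in, phi, jitter, B, f):
    """Kriging weights B and unit-variance conditional variances f.

    Uses the exponential correlation exp(-phi d); the full conditional
    variance is sigma2 * f.  B does not depend on sigma2, which makes the
    sigma2 Metropolis step factor-free.
    """
    n, m = nbr.shape
    for i in range(n):
        k = n_nbr[i]
        for a in range(m):
            B[i, a] = 0.0
        if k == 0:
            f[i] = 1.0 + jitter
            continue
        C = np.empty((k, k))
        c = np.empty(k)
        for a in range(k):
            c[a] = math.exp(-phi * dist_in[i, a])
            for b in range(k):
                C[a, b] = math.exp(-phi * dist_nn[i, a, b])
            C[a, a] += jitter
        Bi = np.linalg.solve(C, c)
        acc = 0.0
        for a in range(k):
            B[i, a] = Bi[a]
            acc += c[a] * Bi[a]
        f[i] = 1.0 + jitter - acc
        if f[i] <= 0.0:
            f[i] = jitter  # numerically degenerate neighbor set


@njit(cache=True)
def nngp_quad(w, nbr, n_nbr, B, f):
    """(sum resid^2 / f, sum log f) for the current kriging factors."""
    n = w.shape[0]
    q = 0.0
    slf = 0.0
    for i in range(n):
        r = w[i]
        for a in range(n_nbr[i]):
            r -= B[i, a] * w[nbr[i, a]]
        q += r * r / f[i]
        slf += math.log(f[i])
    return q, slf


@njit(cache=True)
def nngp_log_density_factors(w, nbr, n_nbr, B, f, sigma2):
    n = w.shape[0]
    q, slf = nngp_quad(w, nbr, n_nbr, B, f)
    return -0.5 * (n * math.log(2.0 * math.pi * sigma2) + slf) - q / (2.0 * sigma2)


# ---------------------------------------------------------------------------
# Conditional Gaussian draws
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sample_mvn_prec(rng, prec, rhs):
    """Draw from N(prec^{-1} rhs, prec^{-1})."""
    p = rhs.shape[0]
    L = np.linalg.cholesky(prec)
    mu = np.linalg.solve(prec, rhs)
    z = np.empty(p)
    for i in range(p):
        z[i] = rng.standard_normal()
    # back-substitution: solve L^T x = z
    x = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = z[i]
        for j in range(i + 1, p):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return mu + x


@njit(cache=True)
def _update_w(rng, w, nbr, n_nbr, B, f, sigma2, dep_ptr, dep_l, dep_pos,
              lik_prec, lik_rhs):
    """Sequential (Gauss-Seidel) draw of each w_i from its full conditional."""
    n = w.shape[0]
    for i in range(n):
        prior_prec = 1.0 / (sigma2 * f[i])
        mean_acc = 0.0
        for t in range(n_nbr[i]):
            mean_acc += B[i, t] * w[nbr[i, t]]
        m_i = prior_prec * mean_acc
        a_i = prior_prec
        for d in range(dep_ptr[i], dep_ptr[i + 1]):
            el = dep_l[d]
            pos = dep_pos[d]
            fl = sigma2 * f[el]
            r = w[el]
            for t in range(n_nbr[el]):
                r -= B[el, t] * w[nbr[el, t]]
            r += B[el, pos] * w[i]  # residual of el excluding i's own term
            a_i += B[el, pos] * B[el, pos] / fl
            m_i += B[el, pos] * r / fl
        prec = a_i + lik_prec[i]
        mean = (m_i + lik_rhs[i]) / prec
        w[i] = mean + rng.standard_normal() / math.sqrt(prec)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def run_chain(
    rng,
    # data
    X, V, y, visit_py, py_point, py_lake, det_any,
    # NNGP structure (rank space)
    nbr, n_nbr, dist_nn, dist_in, dep_ptr, dep_l, dep_pos,
    # priors / bounds
    prior_var, phi_lo, phi_hi, s2_lo, s2_hi, ig_shape, ig_scale, jitter,
    # switches
    include_spatial, include_lakes, n_lakes,
    # mcmc
    n_iter, burn_in, thin, adapt,
):
    """One MCMC chain; returns thinned post-burn-in draws.

    Update order per iteration: z (Gibbs, forced to 1 at detections),
    beta/gamma (Polya-Gamma conjugate), w (sequential NNGP conditionals),
    alpha (Polya-Gamma conjugate over visits with z=1), phi and sigma2
    (Metropolis on logit-transformed scales within their uniform bounds;
    proposal scales adapted during burn-in only), sigma2_lake (conjugate
    inverse-Gamma).
    """
    R, p = X.shape
    S, q = V.shape
    n_pts = nbr.shape[0]
    J = n_lakes

    n_keep = (n_iter - burn_in) // thin
    beta_draws = np.zeros((n_keep, p))
    alpha_draws = np.zeros((n_keep, q))
    gamma_draws = np.zeros((n_keep, J))
    w_draws = np.zeros((n_keep, n_pts))
    phi_draws = np.zeros(n_keep)
    s2_draws = np.zeros(n_keep)
    s2l_draws = np.zeros(n_keep)
    z_mean = np.zeros(R)

    # state
    beta = np.zeros(p)
    alpha = np.zeros(q)
    gamma = np.zeros(J)
    w = np.zeros(n_pts)
    phi = math.sqrt(phi_lo * phi_hi) if include_spatial else 0.0
    sigma2 = min(max(1.0, s2_lo * 1.001), s2_hi * 0.999)
    s2_lake = 1.0
    z = np.zeros(R, dtype=np.int8)
    for r in range(R):
        z[r] = 1 if det_any[r] else (1 if rng.random() < 0.5 else 0)

    m = nbr.shape[1]
    B = np.zeros((n_pts, m))
    f = np.ones(n_pts)
    if include_spatial:
        nngp_unit_factors(nbr, n_nbr, dist_nn, dist_in, phi, jitter, B, f)

    omega = np.empty(R)
    sumlog1mp = np.empty(R)
    xb = X @ beta
    off = np.zeros(R)
    lik_prec = np.zeros(n_pts)
    lik_rhs = np.zeros(n_pts)

    # Metropolis bookkeeping (log proposal sds on the transformed scales)
    ls_phi = math.log(0.5)
    ls_s2 = math.log(0.5)
    acc_phi = 0.0
    acc_s2 = 0.0
    win_phi = 0
    win_s2 = 0
    acc_phi_total = 0.0
    acc_s2_total = 0.0
    n_mh = 0

    kept = 0
    for it in range(n_iter):
        # --- offsets and linear predictors
        for r in range(R):
            o = 0.0
            if include_spatial:
                o += w[py_point[r]]
            if include_lakes:
                o += gamma[py_lake[r]]
            off[r] = o

        # --- detection probabilities and per-row log prod (1 - p)
        for r in range(R):
            sumlog1mp[r] = 0.0
        p_vis = V @ alpha
        for s in range(S):
            pv = _sigmoid(p_vis[s])
            p_vis[s] = pv
            sumlog1mp[visit_py[s]] += math.log1p(-pv)

        # --- z: forced 1 at any detection, else conditional Bernoulli
        for r in range(R):
            if det_any[r]:
                z[r] = 1
            else:
                psi = _sigmoid(xb[r] + off[r])
                num = psi * math.exp(sumlog1mp[r])
                pr = num / (num + 1.0 - psi)
                z[r] = 1 if rng.random() < pr else 0

        # --- occupancy-level Polya-Gamma draws
        for r in range(R):
            omega[r] = pg_draw(rng, xb[r] + off[r])

        # --- beta
        prec = np.zeros((p, p))
        rhs = np.zeros(p)
        for i in range(p):
            prec[i, i] = 1.0 / prior_var
        for r in range(R):
            kappa = z[r] - 0.5
            cr = kappa - omega[r] * off[r]
            for i in range(p):
                xi = X[r, i]
                rhs[i] += xi * cr
                for jcol in range(p):
                    prec[i, jcol] += omega[r] * xi * X[r, jcol]
        beta = _sample_mvn_prec(rng, prec, rhs)
        xb = X @ beta

        # --- gamma (lake intercepts)
        if include_lakes:
            gprec = np.full(J, 1.0 / s2_lake)
            grhs = np.zeros(J)
            for r in range(R):
                jl = py_lake[r]
                rest = xb[r] + (w[py_point[r]] if include_spatial else 0.0)
                gprec[jl] += omega[r]
                grhs[jl] += (z[r] - 0.5) - omega[r] * rest
            for jl in range(J):
                gamma[jl] = grhs[jl] / gprec[jl] + rng.standard_normal() / math.sqrt(
                    gprec[jl]
                )

        # --- w (spatial random effects)
        if include_spatial:
            for i in range(n_pts):
                lik_prec[i] = 0.0
                lik_rhs[i] = 0.0
            for r in range(R):
                i = py_point[r]
                rest = xb[r] + (gamma[py_lake[r]] if include_lakes else 0.0)
                lik_prec[i] += omega[r]
                lik_rhs[i] += (z[r] - 0.5) - omega[r] * rest
            _update_w(rng, w, nbr, n_nbr, B, f, sigma2, dep_ptr, dep_l, dep_pos,
                      lik_prec, lik_rhs)

        # --- alpha (detection; visits at currently occupied point-years only)
        aprec = np.zeros((q, q))
        arhs = np.zeros(q)
        for i in range(q):
            aprec[i, i] = 1.0 / prior_var
        for s in range(S):
            if z[visit_py[s]] == 1:
                eta = 0.0
                for i in range(q):
                    eta += V[s, i] * alpha[i]
                om = pg_draw(rng, eta)
                kappa = y[s] - 0.5
                for i in range(q):
                    vi = V[s, i]
                    arhs[i] += vi * kappa
                    for jcol in range(q):
                        aprec[i, jcol] += om * vi * V[s, jcol]
        alpha = _sample_mvn_prec(rng, aprec, arhs)

        if include_spatial:
            # --- phi: Metropolis on logit((phi-lo)/(hi-lo))
            n_mh += 1
            th = math.log((phi - phi_lo) / (phi_hi - phi))
            th2 = th + math.exp(ls_phi) * rng.standard_normal()
            phi2 = phi_lo + (phi_hi - phi_lo) * _sigmoid(th2)
            B2 = np.zeros((n_pts, m))
            f2 = np.ones(n_pts)
            nngp_unit_factors(nbr, n_nbr, dist_nn, dist_in, phi2, jitter, B2, f2)
            q1, slf1 = nngp_quad(w, nbr, n_nbr, B, f)
            q2, slf2 = nngp_quad(w, nbr, n_nbr, B2, f2)
            lp1 = -0.5 * slf1 - q1 / (2.0 * sigma2)
            lp2 = -0.5 * slf2 - q2 / (2.0 * sigma2)
            jac1 = math.log((phi - phi_lo) * (phi_hi - phi))
            jac2 = math.log((phi2 - phi_lo) * (phi_hi - phi2))
            if math.log(rng.random() + 1e-300) < (lp2 + jac2) - (lp1 + jac1):
                phi = phi2
                B = B2
                f = f2
                acc_phi += 1.0
                acc_phi_total += 1.0
            win_phi += 1

            # --- sigma2: Metropolis, factors unchanged (B free of sigma2)
            qw, _slf = nngp_quad(w, nbr, n_nbr, B, f)
            th = math.log((sigma2 - s2_lo) / (s2_hi - sigma2))
            th2 = th + math.exp(ls_s2) * rng.standard_normal()
            s2b = s2_lo + (s2_hi - s2_lo) * _sigmoid(th2)
            lp1 = -0.5 * n_pts * math.log(sigma2) - qw / (2.0 * sigma2)
            lp2 = -0.5 * n_pts * math.log(s2b) - qw / (2.0 * s2b)
            jac1 = math.log((sigma2 - s2_lo) * (s2_hi - sigma2))
            jac2 = math.log((s2b - s2_lo) * (s2_hi - s2b))
            if math.log(rng.random() + 1e-300) < (lp2 + jac2) - (lp1 + jac1):
                sigma2 = s2b
                acc_s2 += 1.0
                acc_s2_total += 1.0
            win_s2 += 1

            # --- proposal adaptation, burn-in only (Robbins-Monro to 0.44)
            if adapt and it < burn_in and win_phi >= 50:
                ls_phi += 0.5 * (acc_phi / win_phi - 0.44)
                ls_s2 += 0.5 * (acc_s2 / win_s2 - 0.44)
                acc_phi = 0.0
                acc_s2 = 0.0
                win_phi = 0
                win_s2 = 0

        # --- sigma2_lake: conjugate inverse-Gamma
        if include_lakes:
            sh = ig_shape + 0.5 * J
            rate = ig_scale
            for jl in range(J):
                rate += 0.5 * gamma[jl] * gamma[jl]
            s2_lake = rate / rng.gamma(sh, 1.0)

        # --- bookkeeping
        idx = it - burn_in
        if idx >= 0:
            for r in range(R):
                z_mean[r] += z[r]
            if (idx + 1) % thin == 0 and kept < n_keep:
                beta_draws[kept] = beta
                alpha_draws[kept] = alpha
                gamma_draws[kept] = gamma
                w_draws[kept] = w
                phi_draws[kept] = phi
                s2_draws[kept] = sigma2
                s2l_draws[kept] = s2_lake
                kept += 1

    denom = max(n_iter - burn_in, 1)
    for r in range(R):
        z_mean[r] /= denom
    rate_phi = acc_phi_total / max(n_mh, 1)
    rate_s2 = acc_s2_total / max(n_mh, 1)
    return (beta_draws, alpha_draws, gamma_draws, w_draws, phi_draws,
            s2_draws, s2l_draws, z_mean, rate_phi, rate_s2)
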