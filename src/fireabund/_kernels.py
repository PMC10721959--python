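"""Compiled MCMC kernel: component-wise adaptive random-walk Metropolis
within Gibbs for the hierarchical negative-binomial abundance model.

The kernel owns one chain. Parameter layout in the returned draw matrix is

    beta (species-major, S*p) | mu (p) | sigma (p) | sigma_site | r | eps (n_sites)

Updates per sweep: every species coefficient (random-walk Metropolis; the
lgamma terms of the NB pmf cancel when only the mean changes, so each
coefficient update costs only logs/exps over that species' cells), every
site effect, Gibbs draws for the conditionally-Normal community means,
log-scale Metropolis for the community SDs, the site-effect SD and the
dispersion r. Proposal scales adapt by Robbins-Monro toward 0.44
acceptance during burn-in only and are frozen afterwards, preserving the
correct stationary distribution.
"""

import math

import numpy as np
from numba import njit

# layout offsets are computed in sampler.py; the kernel just fills slots


@njit(cache=True)
def run_chain(X, Y, site_ptr, site_rows, pair_cols,
              hierarchical, sample_r, lik_on, shift_move, sample_sites,
              mu_sd, sigma_upper, sigma_site_upper, r_shape, r_rate, beta_sd,
              n_iter, n_burn, thin, seed,
              beta, eps, mu, sigma, sigma_site, r):
    np.random.seed(seed)
    S, p = beta.shape
    R = X.shape[0]
    n_sites = eps.shape[0]
    n_par = S * p + 2 * p + 2 + n_sites
    n_kept = (n_iter - n_burn) // thin
    draws = np.empty((n_kept, n_par))
    acc_count = np.zeros(n_par)

    # cached NB means lambda[i, t]
    lam = np.empty((S, R))
    _recompute_lam(lam, X, beta, eps, site_ptr, site_rows)

    buf = np.empty(R)

    # log proposal scales
    ls_beta = np.full((S, p), math.log(0.1))
    ls_eps = np.full(n_sites, math.log(0.1))
    ls_sig = np.full(p, math.log(0.3))
    ls_ssite = math.log(0.3)
    ls_r = math.log(0.2)
    ls_shift = math.log(0.2)
    ls_nc = math.log(0.3)
    ls_pair = np.full((pair_cols.shape[0], S), math.log(0.2))

    # per-species adaptive joint proposal (empirical-covariance Metropolis):
    # handles posterior correlation between design columns that the
    # component-wise sweep mixes slowly
    ls_joint = np.zeros(S)
    ls_col = np.full(p, math.log(0.1))
    bmean = np.zeros((S, p))
    bM2 = np.zeros((S, p, p))
    bL = np.zeros((S, p, p))
    for i in range(S):
        for c in range(p):
            bL[i, c, c] = 0.02
    joint_ready = 2 * p + 10
    zvec = np.empty(p)
    step = np.empty(p)

    kept = 0
    for it in range(n_iter):
        adapting = it < n_burn
        gam = 2.0 / (it + 20.0) ** 0.6

        # --- species coefficients -------------------------------------
        for i in range(S):
            for c in range(p):
                delta = np.random.normal() * math.exp(ls_beta[i, c])
                b_old = beta[i, c]
                b_new = b_old + delta
                dll = 0.0
                if lik_on == 1:
                    for t in range(R):
                        x = X[t, c]
                        if x != 0.0:
                            lo = lam[i, t]
                            ln = lo * math.exp(delta * x)
                            buf[t] = ln
                            dll += (Y[i, t] * delta * x
                                    - (Y[i, t] + r)
                                    * (math.log(r + ln) - math.log(r + lo)))
                        else:
                            buf[t] = lam[i, t]
                if hierarchical == 1:
                    m = mu[c]
                    sd = sigma[c]
                else:
                    m = 0.0
                    sd = beta_sd
                dlp = -((b_new - m) ** 2 - (b_old - m) ** 2) / (2.0 * sd * sd)
                if math.log(np.random.random()) < dll + dlp:
                    beta[i, c] = b_new
                    if lik_on == 1:
                        for t in range(R):
                            lam[i, t] = buf[t]
                    if not adapting:
                        acc_count[i * p + c] += 1.0
                    a = 1.0
                else:
                    a = 0.0
                if adapting:
                    ls_beta[i, c] += gam * (a - 0.44)

        # --- community column translation -------------------------------
        # shift mu_c and every species' beta_ic together: the species
        # prior terms cancel, so this walks the community-level location
        # (the slow "funnel" direction when sigma_c is small) at the cost
        # of one likelihood pass over the column's nonzero rows.
        if hierarchical == 1:
            for c in range(p):
                delta = np.random.normal() * math.exp(ls_col[c])
                dll = 0.0
                if lik_on == 1:
                    for t in range(R):
                        x = X[t, c]
                        if x != 0.0:
                            de = delta * x
                            f = math.exp(de)
                            for i in range(S):
                                lo = lam[i, t]
                                ln = lo * f
                                dll += (Y[i, t] * de
                                        - (Y[i, t] + r)
                                        * (math.log(r + ln)
                                           - math.log(r + lo)))
                m_new = mu[c] + delta
                dlp = -(m_new * m_new - mu[c] * mu[c]) / (2.0 * mu_sd * mu_sd)
                if math.log(np.random.random()) < dll + dlp:
                    mu[c] = m_new
                    for i in range(S):
                        beta[i, c] += delta
                    if lik_on == 1:
                        for t in range(R):
                            x = X[t, c]
                            if x != 0.0:
                                f = math.exp(delta * x)
                                for i in range(S):
                                    lam[i, t] *= f
                    a = 1.0
                else:
                    a = 0.0
                if adapting:
                    ls_col[c] += gam * (a - 0.44)

        # --- joint coefficient moves per species ------------------------
        # several per sweep: each costs one likelihood pass over the
        # species' cells, cheap next to the p-pass component sweep, and
        # they do most of the work along correlated coefficient directions
        for _rep in range(4 if it >= joint_ready else 0):
            for i in range(S):
                for c in range(p):
                    zvec[c] = np.random.normal()
                sc = math.exp(ls_joint[i])
                for c in range(p):
                    acc_step = 0.0
                    for c2 in range(c + 1):
                        acc_step += bL[i, c, c2] * zvec[c2]
                    step[c] = sc * acc_step
                dll = 0.0
                if lik_on == 1:
                    for t in range(R):
                        de = 0.0
                        for c in range(p):
                            de += step[c] * X[t, c]
                        lo = lam[i, t]
                        ln = lo * math.exp(de)
                        buf[t] = ln
                        dll += (Y[i, t] * de
                                - (Y[i, t] + r)
                                * (math.log(r + ln) - math.log(r + lo)))
                dlp = 0.0
                for c in range(p):
                    if hierarchical == 1:
                        m = mu[c]
                        sd = sigma[c]
                    else:
                        m = 0.0
                        sd = beta_sd
                    b_old = beta[i, c]
                    b_new = b_old + step[c]
                    dlp += -((b_new - m) ** 2 - (b_old - m) ** 2) \
                        / (2.0 * sd * sd)
                if math.log(np.random.random()) < dll + dlp:
                    for c in range(p):
                        beta[i, c] += step[c]
                    if lik_on == 1:
                        for t in range(R):
                            lam[i, t] = buf[t]
                    a = 1.0
                else:
                    a = 0.0
                if adapting:
                    ls_joint[i] += gam * (a - 0.234)

        # running covariance of each species' coefficient vector (burn-in
        # only; the proposal is frozen afterwards so the chain stays valid)
        if adapting:
            nn = float(it + 1)
            for i in range(S):
                for c in range(p):
                    zvec[c] = beta[i, c] - bmean[i, c]
                    bmean[i, c] += zvec[c] / nn
                for c in range(p):
                    d2 = beta[i, c] - bmean[i, c]
                    for c2 in range(p):
                        bM2[i, c2, c] += zvec[c2] * d2
            if (it + 1) % 50 == 0 and it + 1 >= joint_ready:
                fac = 2.38 * 2.38 / p
                covm = np.empty((p, p))
                for i in range(S):
                    for c in range(p):
                        for c2 in range(p):
                            covm[c, c2] = bM2[i, c, c2] / (nn - 1.0) * fac
                        covm[c, c] += 1e-9
                    bL[i] = np.linalg.cholesky(covm)

        # --- pairwise coefficient exchanges -----------------------------
        # column pairs (c_a, c_b) whose design values coincide on most
        # rows (upland indicator vs intercept; burn-by-upland vs burn):
        # moving beta_ia up and beta_ib down leaves those rows' means
        # unchanged, so the likelihood pass touches only the remaining
        # (meadow) rows — a cheap walk along an otherwise slow ridge.
        for pr in range(pair_cols.shape[0]):
            ca = pair_cols[pr, 0]
            cb = pair_cols[pr, 1]
            for i in range(S):
                delta = np.random.normal() * math.exp(ls_pair[pr, i])
                dll = 0.0
                if lik_on == 1:
                    for t in range(R):
                        dx = X[t, ca] - X[t, cb]
                        if dx != 0.0:
                            de = delta * dx
                            lo = lam[i, t]
                            ln = lo * math.exp(de)
                            buf[t] = ln
                            dll += (Y[i, t] * de
                                    - (Y[i, t] + r)
                                    * (math.log(r + ln) - math.log(r + lo)))
                        else:
                            buf[t] = lam[i, t]
                if hierarchical == 1:
                    ma = mu[ca]
                    sa = sigma[ca]
                    mb = mu[cb]
                    sb = sigma[cb]
                else:
                    ma = 0.0
                    sa = beta_sd
                    mb = 0.0
                    sb = beta_sd
                a_new = beta[i, ca] + delta
                b_new = beta[i, cb] - delta
                dlp = (-((a_new - ma) ** 2 - (beta[i, ca] - ma) ** 2)
                       / (2.0 * sa * sa)
                       - ((b_new - mb) ** 2 - (beta[i, cb] - mb) ** 2)
                       / (2.0 * sb * sb))
                if math.log(np.random.random()) < dll + dlp:
                    beta[i, ca] = a_new
                    beta[i, cb] = b_new
                    if lik_on == 1:
                        for t in range(R):
                            lam[i, t] = buf[t]
                    a = 1.0
                else:
                    a = 0.0
                if adapting:
                    ls_pair[pr, i] += gam * (a - 0.44)

        # --- site effects (two sweeps: a full pass is cheap — every cell
        # belongs to exactly one site) -----------------------------------
        for ss in range(2 * (n_sites if sample_sites == 1 else 0)):
            s = ss % n_sites
            delta = np.random.normal() * math.exp(ls_eps[s])
            factor = math.exp(delta)
            dll = 0.0
            if lik_on == 1:
                for idx in range(site_ptr[s], site_ptr[s + 1]):
                    t = site_rows[idx]
                    for i in range(S):
                        lo = lam[i, t]
                        ln = lo * factor
                        dll += (Y[i, t] * delta
                                - (Y[i, t] + r)
                                * (math.log(r + ln) - math.log(r + lo)))
            e_old = eps[s]
            e_new = e_old + delta
            dlp = -(e_new * e_new - e_old * e_old) / (2.0 * sigma_site * sigma_site)
            if math.log(np.random.random()) < dll + dlp:
                eps[s] = e_new
                if lik_on == 1:
                    for idx in range(site_ptr[s], site_ptr[s + 1]):
                        t = site_rows[idx]
                        for i in range(S):
                            lam[i, t] *= factor
                if not adapting:
                    # two sweeps per iteration share one reporting slot
                    acc_count[S * p + 2 * p + 2 + s] += 0.5
                a = 1.0
            else:
                a = 0.0
            if adapting:
                ls_eps[s] += gam * (a - 0.44)

        # --- intercept/site-effect translation move ---------------------
        # eta depends on beta_i0 + eps_s only through their sum, so shifting
        # all eps by delta and all intercepts by -delta leaves the
        # likelihood invariant; accepting on the prior ratio alone mixes
        # the otherwise slow ridge between the two.
        if shift_move == 1:
            delta = np.random.normal() * math.exp(ls_shift)
            d = 0.0
            for s in range(n_sites):
                e_new = eps[s] + delta
                d += -(e_new * e_new - eps[s] * eps[s]) \
                    / (2.0 * sigma_site * sigma_site)
            if hierarchical == 1:
                m0 = mu[0]
                s0 = sigma[0]
            else:
                m0 = 0.0
                s0 = beta_sd
            for i in range(S):
                b_new = beta[i, 0] - delta
                d += -((b_new - m0) ** 2 - (beta[i, 0] - m0) ** 2) \
                    / (2.0 * s0 * s0)
            if math.log(np.random.random()) < d:
                for s in range(n_sites):
                    eps[s] += delta
                for i in range(S):
                    beta[i, 0] -= delta
                a = 1.0
            else:
                a = 0.0
            if adapting:
                ls_shift += gam * (a - 0.44)

        # --- community hyper-means: Gibbs (Normal-Normal) --------------
        if hierarchical == 1:
            for c in range(p):
                prec = S / (sigma[c] * sigma[c]) + 1.0 / (mu_sd * mu_sd)
                sm = 0.0
                for i in range(S):
                    sm += beta[i, c]
                mean = (sm / (sigma[c] * sigma[c])) / prec
                mu[c] = mean + np.random.normal() / math.sqrt(prec)
            # --- community hyper-SDs: log-scale Metropolis -------------
            for c in range(p):
                ls_old = math.log(sigma[c])
                ls_new = ls_old + np.random.normal() * math.exp(ls_sig[c])
                s_new = math.exp(ls_new)
                a = 0.0
                if s_new < sigma_upper:
                    q = 0.0
                    for i in range(S):
                        q += (beta[i, c] - mu[c]) ** 2
                    d = (-0.5 * q * (1.0 / (s_new * s_new)
                                     - 1.0 / (sigma[c] * sigma[c]))
                         - S * (ls_new - ls_old)
                         + (ls_new - ls_old))  # Jacobian of log transform
                    if math.log(np.random.random()) < d:
                        sigma[c] = s_new
                        a = 1.0
                        if not adapting:
                            acc_count[S * p + p + c] += 1.0
                if adapting:
                    ls_sig[c] += gam * (a - 0.44)

        # --- site-effect SD --------------------------------------------
        if sample_sites == 1:
            ls_old = math.log(sigma_site)
            ls_new = ls_old + np.random.normal() * math.exp(ls_ssite)
            s_new = math.exp(ls_new)
            a = 0.0
            if s_new < sigma_site_upper:
                q = 0.0
                for s in range(n_sites):
                    q += eps[s] * eps[s]
                d = (-0.5 * q * (1.0 / (s_new * s_new)
                                 - 1.0 / (sigma_site * sigma_site))
                     - n_sites * (ls_new - ls_old) + (ls_new - ls_old))
                if math.log(np.random.random()) < d:
                    sigma_site = s_new
                    a = 1.0
                    if not adapting:
                        acc_count[S * p + 2 * p] += 1.0
            if adapting:
                ls_ssite += gam * (a - 0.44)

        # --- non-centered site-SD rescaling (interweaving) --------------
        # with u = eps/sigma_site held fixed (u ~ N(0,1) a priori), a
        # log-walk on sigma_site rescales every site effect jointly,
        # breaking the funnel between sigma_site and eps; acceptance is
        # the likelihood ratio plus the log-transform Jacobian (the
        # uniform prior on sigma_site cancels).
        if sample_sites == 1:
            ls_old = math.log(sigma_site)
            ls_new = ls_old + np.random.normal() * math.exp(ls_nc)
            s_new = math.exp(ls_new)
            a = 0.0
            if s_new < sigma_site_upper:
                ratio = s_new / sigma_site
                dll = 0.0
                if lik_on == 1:
                    for s in range(n_sites):
                        de = eps[s] * (ratio - 1.0)
                        f = math.exp(de)
                        for idx in range(site_ptr[s], site_ptr[s + 1]):
                            t = site_rows[idx]
                            for i in range(S):
                                lo = lam[i, t]
                                ln = lo * f
                                dll += (Y[i, t] * de
                                        - (Y[i, t] + r)
                                        * (math.log(r + ln)
                                           - math.log(r + lo)))
                if math.log(np.random.random()) < dll + (ls_new - ls_old):
                    for s in range(n_sites):
                        de = eps[s] * (ratio - 1.0)
                        f = math.exp(de)
                        if lik_on == 1:
                            for idx in range(site_ptr[s], site_ptr[s + 1]):
                                t = site_rows[idx]
                                for i in range(S):
                                    lam[i, t] *= f
                        eps[s] *= ratio
                    sigma_site = s_new
                    a = 1.0
            if adapting:
                ls_nc += gam * (a - 0.44)

        # --- dispersion r ----------------------------------------------
        if sample_r == 1:
            lr_old = math.log(r)
            lr_new = lr_old + np.random.normal() * math.exp(ls_r)
            r_new = math.exp(lr_new)
            d = 0.0
            if lik_on == 1:
                for i in range(S):
                    for t in range(R):
                        lo = lam[i, t]
                        d += (math.lgamma(Y[i, t] + r_new)
                              - math.lgamma(Y[i, t] + r)
                              + r_new * math.log(r_new / (r_new + lo))
                              - r * math.log(r / (r + lo))
                              - Y[i, t] * (math.log(r_new + lo)
                                           - math.log(r + lo)))
                d -= S * R * (math.lgamma(r_new) - math.lgamma(r))
            # Gamma(shape, rate) prior + log-transform Jacobian
            d += r_shape * (lr_new - lr_old) - r_rate * (r_new - r)
            a = 0.0
            if math.log(np.random.random()) < d:
                r = r_new
                a = 1.0
                if not adapting:
                    acc_count[S * p + 2 * p + 1] += 1.0
            if adapting:
                ls_r += gam * (a - 0.44)

        # periodic refresh kills accumulated multiplicative FP drift
        if lik_on == 1 and (it + 1) % 500 == 0:
            _recompute_lam(lam, X, beta, eps, site_ptr, site_rows)

        # --- store ------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            k = 0
            for i in range(S):
                for c in range(p):
                    draws[kept, k] = beta[i, c]
                    k += 1
            for c in range(p):
                draws[kept, k] = mu[c]
                k += 1
            for c in range(p):
                draws[kept, k] = sigma[c]
                k += 1
            draws[kept, k] = sigma_site
            draws[kept, k + 1] = r
            k += 2
            for s in range(n_sites):
                draws[kept, k] = eps[s]
                k += 1
            kept += 1

    n_post = n_iter - n_burn
    acc = acc_count / max(1, n_post)
    if hierarchical == 1:
        for c in range(p):
            acc[S * p + c] = 1.0  # Gibbs draws always accept
    return draws, acc


@njit(cache=True)
def _recompute_lam(lam, X, beta, eps, site_ptr, site_rows):
    S, p = beta.shape
    R = X.shape[0]
    n_sites = site_ptr.shape[0] - 1
    site_of = np.empty(R, dtype=np.int64)
    for s in range(n_sites):
        for idx in range(site_ptr[s], site_ptr[s + 1]):
            site_of[site_rows[idx]] = s
    for i in range(S):
        for t in range(R):
            eta = eps[site_of[t]]
            for c in range(p):
                eta += beta[i, c] * X[t, c]
            lam[i, t] = math.exp(eta)
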