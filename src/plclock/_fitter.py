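"""Numba kernels for the penalized-likelihood discrete-clock fit.

The optimizer is a block-coordinate ascent over three blocks, each of which
maximizes the penalized objective exactly with the other blocks held fixed,
so every accepted iteration is monotonically non-decreasing:

1. category reassignment — sequential iterated conditional modes over
   branches; ties broken toward the lowest category index;
2. category rates — each category's log-rate solves a strictly concave 1-D
   problem (closed first-order condition, solved by bisection);
3. node ages — coordinate ascent over internal nodes; each node's age
   maximizes a strictly concave 1-D section (bisection on the derivative)
   inside its feasible interval.

All arrays are indexed in tree preorder with the root at 0; "branch i" means
the branch subtending node i (so branch 0 does not exist).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -math.inf

# Relative margin keeping tip-ward durations strictly positive; expressed as
# a fraction of the current root age.
DUR_MARGIN = 1e-8


@njit(cache=True)
def objective_kernel(parent, x, cat, rates, ages, s, lam, pairs):
    """Return (objective, loglik, penalty).

    loglik is the continuous-Poisson log-likelihood of the observed
    substitution counts x_i = b_i * s given mu_i = r_{c(i)} * d_i * s;
    penalty is the sum of squared log-rate differences across adjacent
    branch pairs.  A zero duration on a branch with x > 0 yields -inf
    (signalled, not crashed).
    """
    n = parent.shape[0]
    ll = 0.0
    for i in range(1, n):
        d = ages[parent[i]] - ages[i]
        mu = rates[cat[i]] * d * s
        if x[i] > 0.0:
            if mu <= 0.0:
                return NEG_INF, NEG_INF, 0.0
            ll += x[i] * math.log(mu) - mu - math.lgamma(x[i] + 1.0)
        else:
            ll += -mu
    pen = 0.0
    for p in range(pairs.shape[0]):
        diff = math.log(rates[cat[pairs[p, 0]]]) - math.log(rates[cat[pairs[p, 1]]])
        pen += diff * diff
    return ll - lam * pen, ll, pen


@njit(cache=True)
def _reassign(parent, x, cat, rates, ages, s, lam, part_ptr, part_idx):
    """One ICM sweep of category reassignment; returns True if any change."""
    n = parent.shape[0]
    k = rates.shape[0]
    lrates = np.empty(k)
    for c in range(k):
        lrates[c] = math.log(rates[c])
    changed = False
    for i in range(1, n):
        d = ages[parent[i]] - ages[i]
        if d <= 0.0 and x[i] > 0.0:
            continue  # every candidate is -inf; keep current
        best_c = cat[i]
        best = NEG_INF
        for c in range(k):
            r = rates[c]
            mu = r * d * s
            if x[i] > 0.0:
                sc = x[i] * math.log(mu) - mu
            else:
                sc = -mu
            lr = lrates[c]
            for t in range(part_ptr[i], part_ptr[i + 1]):
                diff = lr - lrates[cat[part_idx[t]]]
                sc -= lam * diff * diff
            if sc > best:
                best = sc
                best_c = c
        if best_c != cat[i]:
            cat[i] = best_c
            changed = True
    return changed


@njit(cache=True)
def _update_rates(parent, x, cat, rates, ages, s, lam, pairs, rate_floor):
    """Exact coordinate maximization of each category's rate (in log space)."""
    n = parent.shape[0]
    k = rates.shape[0]
    lo_r = math.log(rate_floor)
    hi_r = -lo_r
    for j in range(k):
        X = 0.0
        T = 0.0
        used = False
        for i in range(1, n):
            if cat[i] == j:
                used = True
                X += x[i]
                T += ages[parent[i]] - ages[i]
        npairs = 0.0
        M = 0.0
        for p in range(pairs.shape[0]):
            ca = cat[pairs[p, 0]]
            cb = cat[pairs[p, 1]]
            if ca == j and cb != j:
                npairs += 1.0
                M += math.log(rates[cb])
            elif cb == j and ca != j:
                npairs += 1.0
                M += math.log(rates[ca])
        if not used and npairs == 0.0:
            continue  # empty, uncoupled category: leave its rate alone
        # f'(rho) = X - s*T*exp(rho) - 2*lam*(npairs*rho - M), decreasing
        lo = lo_r
        hi = hi_r
        flo = X - s * T * math.exp(lo) - 2.0 * lam * (npairs * lo - M)
        fhi = X - s * T * math.exp(hi) - 2.0 * lam * (npairs * hi - M)
        if flo <= 0.0:
            rho = lo
        elif fhi >= 0.0:
            rho = hi
        else:
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                fm = X - s * T * math.exp(mid) - 2.0 * lam * (npairs * mid - M)
                if fm > 0.0:
                    lo = mid
                else:
                    hi = mid
            rho = 0.5 * (lo + hi)
        rates[j] = math.exp(rho)


@njit(cache=True)
def _age_sweep(
    parent, child_ptr, child_idx, is_tip, x, cat, rates, ages, s, lo_box, hi_box
):
    """One coordinate-ascent sweep over internal-node ages."""
    n = parent.shape[0]
    margin = DUR_MARGIN * ages[0]
    for v in range(n):
        if is_tip[v]:
            continue
        mc = 0.0
        for t in range(child_ptr[v], child_ptr[v + 1]):
            c = child_idx[t]
            if ages[c] > mc:
                mc = ages[c]
        L = lo_box[v]
        if mc > L:
            L = mc
        if v == 0:
            U = hi_box[0]
        else:
            U = hi_box[v]
            if ages[parent[v]] < U:
                U = ages[parent[v]]
        # keep tip-ward durations strictly positive where the box allows
        if mc + margin > L and mc + margin < U:
            L = mc + margin
        if U <= L:
            ages[v] = L
            continue
        span = U - L
        delta = 1e-12 * span
        floor_delta = 1e-15 * (abs(L) + abs(U) + 1.0)
        if delta < floor_delta:
            delta = floor_delta
        a_lo = L + delta
        a_hi = U - delta
        if a_hi <= a_lo:
            ages[v] = 0.5 * (L + U)
            continue
        # g'(a) = sum_c x_c/(a - a_c) - x_v/(a_p - a) + s*(r_v - sum_c r_c)
        beta = 0.0
        if v != 0:
            beta += s * rates[cat[v]]
        for t in range(child_ptr[v], child_ptr[v + 1]):
            c = child_idx[t]
            beta -= s * rates[cat[c]]
        g_lo = _age_deriv(v, a_lo, parent, child_ptr, child_idx, x, ages, beta)
        if g_lo <= 0.0:
            ages[v] = a_lo
            continue
        g_hi = _age_deriv(v, a_hi, parent, child_ptr, child_idx, x, ages, beta)
        if g_hi >= 0.0:
            ages[v] = a_hi
            continue
        lo = a_lo
        hi = a_hi
        for _ in range(45):
            mid = 0.5 * (lo + hi)
            if _age_deriv(v, mid, parent, child_ptr, child_idx, x, ages, beta) > 0.0:
                lo = mid
            else:
                hi = mid
        ages[v] = 0.5 * (lo + hi)


@njit(cache=True)
def _age_deriv(v, a, parent, child_ptr, child_idx, x, ages, beta):
    g = beta
    for t in range(child_ptr[v], child_ptr[v + 1]):
        c = child_idx[t]
        if x[c] > 0.0:
            d = a - ages[c]
            if d <= 0.0:
                return math.inf
            g += x[c] / d
    if v != 0 and x[v] > 0.0:
        d = ages[parent[v]] - a
        if d <= 0.0:
            return -math.inf
        g -= x[v] / d
    return g


@njit(cache=True)
def _rescale_ages(parent, is_tip, x, cat, rates, ages, s, lo_box, hi_box):
    """Exact line search along the global time-rescaling direction.

    Scaling every free age by c leaves the penalty and the age ordering
    untouched; the log-likelihood is X*log(c) - c*sum(mu) + const, maximized
    at c* = X / sum(mu), then clipped so every node stays in its box.  This
    direction is nearly flat for the coordinate sweeps and would otherwise
    dominate the iteration count.
    """
    n = parent.shape[0]
    X = 0.0
    mu_sum = 0.0
    for i in range(1, n):
        d = ages[parent[i]] - ages[i]
        X += x[i]
        mu_sum += rates[cat[i]] * d * s
    if mu_sum <= 0.0 or X <= 0.0:
        return
    c = X / mu_sum
    c_lo = 0.0
    c_hi = math.inf
    for v in range(n):
        if is_tip[v] or ages[v] <= 0.0:
            continue
        if lo_box[v] > 0.0:
            r = lo_box[v] / ages[v]
            if r > c_lo:
                c_lo = r
        if math.isfinite(hi_box[v]):
            r = hi_box[v] / ages[v]
            if r < c_hi:
                c_hi = r
    if c < c_lo:
        c = c_lo
    if c > c_hi:
        c = c_hi
    if c != 1.0 and c > 0.0 and math.isfinite(c):
        for v in range(n):
            if not is_tip[v]:
                ages[v] = ages[v] * c


@njit(cache=True)
def _project_ages(parent, is_tip, ages, lo_box, hi_box):
    """Clip ages into calibration boxes and parent >= child (preorder)."""
    n = parent.shape[0]
    for v in range(n):
        if is_tip[v]:
            continue
        a = ages[v]
        if a < lo_box[v]:
            a = lo_box[v]
        hi = hi_box[v]
        if v != 0 and ages[parent[v]] < hi:
            hi = ages[parent[v]]
        if a > hi:
            a = hi
        ages[v] = a


@njit(cache=True)
def fit_kernel(
    parent,
    child_ptr,
    child_idx,
    is_tip,
    x,
    lo_box,
    hi_box,
    pairs,
    part_ptr,
    part_idx,
    s,
    lam,
    ages,
    cat,
    rates,
    tol,
    max_iter,
    rate_floor,
):
    """Run block-coordinate ascent in place; return (obj, ll, pen, iters, conv).

    Every block update is an exact 1-D/ICM maximization, so iterations are
    monotone.  A projected extrapolation along the last step direction is
    attempted each iteration and kept only when it improves the objective
    (the coordinate sweeps otherwise crawl along flat rate-time valleys).
    """
    n = parent.shape[0]
    k = rates.shape[0]
    obj, ll, pen = objective_kernel(parent, x, cat, rates, ages, s, lam, pairs)
    prev_ages = ages.copy()
    prev_lr = np.empty(k)
    cand_ages = np.empty(n)
    cand_rates = np.empty(k)
    lo_r = math.log(rate_floor)
    alpha = 4.0  # adaptive extrapolation factor
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(k):
            prev_lr[j] = math.log(rates[j])
        for v in range(n):
            prev_ages[v] = ages[v]
        _reassign(parent, x, cat, rates, ages, s, lam, part_ptr, part_idx)
        _update_rates(parent, x, cat, rates, ages, s, lam, pairs, rate_floor)
        for _ in range(2):
            _age_sweep(
                parent, child_ptr, child_idx, is_tip, x, cat, rates, ages, s,
                lo_box, hi_box,
            )
            _rescale_ages(parent, is_tip, x, cat, rates, ages, s, lo_box, hi_box)
        new_obj, ll, pen = objective_kernel(parent, x, cat, rates, ages, s, lam, pairs)
        if math.isfinite(new_obj):
            for v in range(n):
                cand_ages[v] = ages[v] + alpha * (ages[v] - prev_ages[v])
            _project_ages(parent, is_tip, cand_ages, lo_box, hi_box)
            for j in range(k):
                lr = math.log(rates[j])
                lr = lr + alpha * (lr - prev_lr[j])
                if lr < lo_r:
                    lr = lo_r
                elif lr > -lo_r:
                    lr = -lo_r
                cand_rates[j] = math.exp(lr)
            c_obj, c_ll, c_pen = objective_kernel(
                parent, x, cat, cand_rates, cand_ages, s, lam, pairs
            )
            if c_obj > new_obj:
                for v in range(n):
                    ages[v] = cand_ages[v]
                for j in range(k):
                    rates[j] = cand_rates[j]
                new_obj, ll, pen = c_obj, c_ll, c_pen
                if alpha < 32.0:
                    alpha *= 2.0
            elif alpha > 2.0:
                alpha *= 0.5
        if math.isfinite(new_obj) and math.isfinite(obj):
            if abs(new_obj - obj) <= tol * max(1.0, abs(new_obj)):
                obj = new_obj
                converged = True
                break
        obj = new_obj
    return obj, ll, pen, it, converged
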