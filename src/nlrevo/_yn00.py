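"""Yang & Nielsen (2000)-style pairwise dN/dS estimation.

Kappa is estimated from nondegenerate and fourfold-degenerate codon positions
(F84 correction, converted to HKY form); synonymous and nonsynonymous sites
are counted with mutation-rate weights (target-codon frequency times kappa
for transitions); observed differences are partitioned into transitions and
transversions per site class, weighting multi-step codon pathways by their
probability under a GY94-style codon model; distances are corrected with the
F84 formula per class and the whole procedure is iterated until dS and dN
stabilise.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from scipy.linalg import expm

from ._codons import BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, is_transition

_ALL_CODONS = tuple(SENSE_CODONS) + tuple(sorted(STOP_CODONS))
_CODON_INDEX = {c: i for i, c in enumerate(_ALL_CODONS)}

_TOL = 1e-5
_FALLBACK_KAPPA = 2.0


def _fold_class(codon: str) -> str:
    """Three-character degeneracy string, one of '0'/'2'/'4' per position."""
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if nb not in STOP_CODONS and CODON_TO_AA[nb] == aa:
                syn += 1
        out.append("4" if syn == 3 else ("0" if syn == 0 else "2"))
    return "".join(out)


_FOLD = {c: _fold_class(c) for c in SENSE_CODONS}


def _f84(freq: dict[str, float], P: float, Q: float):
    """F84 correction: returns (kappa_F84, distance) or None if undefined."""
    piT, piC, piA, piG = freq["T"], freq["C"], freq["A"], freq["G"]
    piY, piR = piT + piC, piA + piG
    if piY <= 0 or piR <= 0:
        return None
    tc, ag = piT * piC, piA * piG
    denom = 2.0 * (tc / piY + ag / piR)
    if denom <= 0:
        return None
    B = 1.0 - Q / (2.0 * piY * piR)
    if B <= 0:
        return None
    A = (
        2.0 * (tc + ag)
        + 2.0 * (tc * piR / piY + ag * piY / piR) * (1.0 - Q / (2.0 * piY * piR))
        - P
    ) / denom
    if A <= 0:
        return None
    a = -0.5 * math.log(A)
    b = -0.5 * math.log(B)
    if b == 0:
        kf84 = 0.0
    else:
        kf84 = a / b - 1.0
    dist = (
        4.0 * tc * (1.0 + kf84 / piY)
        + 4.0 * ag * (1.0 + kf84 / piR)
        + 4.0 * piY * piR
    ) * b
    return kf84, dist


def _hky_kappa(freq: dict[str, float], P: float, Q: float) -> float | None:
    res = _f84(freq, P, Q)
    if res is None:
        return None
    kf84, _ = res
    piY = freq["T"] + freq["C"]
    piR = freq["A"] + freq["G"]
    tc, ag = freq["T"] * freq["C"], freq["A"] * freq["G"]
    if tc + ag <= 0:
        return None
    return 1.0 + (tc / piY + ag / piR) * kf84 / (tc + ag)


def _estimate_kappa(pairs) -> float:
    """Kappa (HKY) from nondegenerate and fourfold-degenerate positions."""
    fold0 = {b: 0.0 for b in "TCAG"}
    fold4 = {b: 0.0 for b in "TCAG"}
    ts = tv = sites = 0
    for x, y in pairs:
        for pos in range(3):
            bx, by = x[pos], y[pos]
            sites += 1
            if bx != by:
                if is_transition(bx, by):
                    ts += 1
                else:
                    tv += 1
        for codon in (x, y):
            f = _FOLD[codon]
            for pos in range(3):
                if f[pos] == "0":
                    fold0[codon[pos]] += 1
                elif f[pos] == "4":
                    fold4[codon[pos]] += 1
    if sites == 0:
        return _FALLBACK_KAPPA
    P, Q = ts / sites, tv / sites
    total0, total4 = sum(fold0.values()), sum(fold4.values())
    acc = wsum = 0.0
    for freq, weight in ((fold0, total0), (fold4, total4)):
        if weight <= 0:
            continue
        norm = {b: v / weight for b, v in freq.items()}
        k = _hky_kappa(norm, P, Q)
        if k is not None and math.isfinite(k) and k > 0:
            acc += weight * k
            wsum += weight
    return acc / wsum if wsum > 0 else _FALLBACK_KAPPA


def _count_sites_one(codons, pi, kappa):
    """Mutation-weighted S/N site counts for one sequence, normalised to 3L."""
    S = N = 0.0
    freq_syn = {b: 0.0 for b in "TCAG"}
    freq_non = {b: 0.0 for b in "TCAG"}
    for codon in codons:
        aa = CODON_TO_AA[codon]
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                nb = codon[:pos] + b + codon[pos + 1 :]
                if nb in STOP_CODONS:
                    continue
                w = pi[nb]
                if is_transition(codon[pos], b):
                    w *= kappa
                if CODON_TO_AA[nb] == aa:
                    S += w
                    freq_syn[b] += w
                else:
                    N += w
                    freq_non[b] += w
    if S + N <= 0:
        raise ValueError("degenerate site counts (no mutable positions)")
    scale = 3.0 * len(codons) / (S + N)
    S *= scale
    N *= scale
    for freq in (freq_syn, freq_non):
        tot = sum(freq.values())
        if tot > 0:
            for b in freq:
                freq[b] /= tot
    return S, N, freq_syn, freq_non


def _count_sites(pairs, pi, kappa):
    """S/N site counts and per-class target-base freqs, averaged over the
    two sequences."""
    s1, n1, fs1, fn1 = _count_sites_one([x for x, _ in pairs], pi, kappa)
    s2, n2, fs2, fn2 = _count_sites_one([y for _, y in pairs], pi, kappa)
    freq_syn = {b: (fs1[b] + fs2[b]) / 2.0 for b in "TCAG"}
    freq_non = {b: (fn1[b] + fn2[b]) / 2.0 for b in "TCAG"}
    return (s1 + s2) / 2.0, (n1 + n2) / 2.0, freq_syn, freq_non


def _gy94_q(pi_codon: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    n = len(_ALL_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(_ALL_CODONS):
        for j, cj in enumerate(_ALL_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = pi_codon[j]
            if is_transition(ci[k], cj[k]):
                rate *= kappa
            if ci in STOP_CODONS or cj in STOP_CODONS:
                rate = 0.0
            elif CODON_TO_AA[ci] != CODON_TO_AA[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    mean_rate = float(np.dot(pi_codon, -np.diag(Q)))
    if mean_rate > 0:
        Q /= mean_rate
    return Q


def _step_counts(cur: str, nxt: str, pos: int):
    """(index, weight-class) for one single-base step: 0 syn-ts, 1 syn-tv,
    2 nonsyn-ts, 3 nonsyn-tv.  Stops count as nonsynonymous."""
    ts = is_transition(cur[pos], nxt[pos])
    if cur in STOP_CODONS or nxt in STOP_CODONS:
        syn = False
    else:
        syn = CODON_TO_AA[cur] == CODON_TO_AA[nxt]
    if syn:
        return 0 if ts else 1
    return 2 if ts else 3


def _count_differences(pairs, P: np.ndarray):
    """Pathway-weighted (syn-ts, syn-tv, nonsyn-ts, nonsyn-tv) totals."""
    totals = [0.0, 0.0, 0.0, 0.0]
    for x, y in pairs:
        if x == y:
            continue
        diff = [k for k in range(3) if x[k] != y[k]]
        paths = []
        probs = []
        for order in permutations(diff):
            cur = x
            legs = []
            prob = 1.0
            for pos in order:
                nxt = cur[:pos] + y[pos] + cur[pos + 1 :]
                legs.append((cur, nxt, pos))
                prob *= P[_CODON_INDEX[cur], _CODON_INDEX[nxt]]
                cur = nxt
            paths.append(legs)
            probs.append(prob)
        total_p = sum(probs)
        if total_p <= 0:
            # all pathways numerically impossible; weight stop-free ones evenly
            keep = [
                k for k, legs in enumerate(paths)
                if all(nxt not in STOP_CODONS for _, nxt, _ in legs)
            ] or list(range(len(paths)))
            probs = [1.0 if k in keep else 0.0 for k in range(len(paths))]
            total_p = float(sum(probs))
        for legs, prob in zip(paths, probs):
            w = prob / total_p
            for cur, nxt, pos in legs:
                totals[_step_counts(cur, nxt, pos)] += w
    return totals


def yn00_pair(pairs, max_iter: int = 50):
    """Estimate dN/dS for a list of comparable sense-codon pairs.

    Returns a :class:`nlrevo.codondiv.PairDivergence`.
    """
    from .codondiv import PairDivergence  # local import to avoid a cycle

    n_codons = len(pairs)
    counts = {c: 0.0 for c in _ALL_CODONS}
    for x, y in pairs:
        counts[x] += 1.0
        counts[y] += 1.0
    total = sum(counts.values())
    pi = {c: v / total for c, v in counts.items()}
    pi_vec = np.array([pi[c] for c in _ALL_CODONS])

    kappa = _estimate_kappa(pairs)
    try:
        S, N, freq_syn, freq_non = _count_sites(pairs, pi, kappa)
    except ValueError:
        # observed-codon weighting can vanish on tiny inputs whose codons
        # have no observed neighbours; fall back to uniform codon weights
        uniform = {c: 1.0 for c in _ALL_CODONS}
        for c in STOP_CODONS:
            uniform[c] = 0.0
        S, N, freq_syn, freq_non = _count_sites(pairs, uniform, kappa)

    if all(x == y for x, y in pairs):
        return PairDivergence(
            dN=0.0, dS=0.0, omega=math.nan, S_sites=S, N_sites=N,
            Sd=0.0, Nd=0.0, n_codons=n_codons, valid=True,
        )

    # NG86-flavoured starting values for t and omega
    from ._codons import SN_SITES, pair_sdnd

    sd0 = nd0 = 0.0
    for x, y in pairs:
        sd, nd = pair_sdnd(x, y)
        sd0 += sd
        nd0 += nd
    p_all = (sd0 + nd0) / (3.0 * n_codons)
    t = 1.0 if p_all >= 0.75 else -0.75 * math.log(1.0 - 4.0 * p_all / 3.0) * 3.0
    t = max(t, 1e-4)
    omega = 0.5

    dS_prev = dN_prev = None
    dS = dN = math.nan
    Sd = Nd = math.nan
    converged = False
    for _ in range(max_iter):
        Q = _gy94_q(pi_vec, kappa, omega)
        P = expm(Q * t)
        s_ts, s_tv, n_ts, n_tv = _count_differences(pairs, P)
        Sd, Nd = s_ts + s_tv, n_ts + n_tv
        res_s = _f84(freq_syn, s_ts / S, s_tv / S)
        res_n = _f84(freq_non, n_ts / N, n_tv / N)
        if res_s is None or res_n is None:
            return PairDivergence(
                dN=math.nan, dS=math.nan, omega=math.nan, S_sites=S, N_sites=N,
                Sd=Sd, Nd=Nd, n_codons=n_codons, valid=False,
            )
        dS, dN = res_s[1], res_n[1]
        if dS <= 0 and dN <= 0:
            break
        t = (dS * 3.0 * S + dN * 3.0 * N) / (S + N)
        t = max(t, 1e-6)
        omega = dN / dS if dS > 0 else 10.0
        if dS_prev is not None and abs(dS - dS_prev) < _TOL and abs(dN - dN_prev) < _TOL:
            converged = True
            break
        dS_prev, dN_prev = dS, dN

    valid = converged or (dS == 0.0 and dN == 0.0)
    omega_out = dN / dS if valid and dS > 0 else math.nan
    return PairDivergence(
        dN=dN, dS=dS, omega=omega_out, S_sites=S, N_sites=N,
        Sd=Sd, Nd=Nd, n_codons=n_codons, valid=valid,
    )
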