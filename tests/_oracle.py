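"""Literal scalar reference implementation of the growth equations.

Loops over every cell and type applying the heterospecific load, the
competition-dependent resource uptake and the Maynard Smith-Slatkin map
directly, with no vectorization and no code shared with the engine.  Used to
cross-check the vectorized growth step on small random instances.
"""

from __future__ import annotations

import numpy as np


def _overlap(p1: str, p2: str) -> bool:
    return p1 == p2 or p1 == "both" or p2 == "both"


def _in_range(r, c, rr, cc, radius) -> bool:
    return (rr - r) ** 2 + (cc - c) ** 2 <= radius * radius


def oracle_growth_step(
    N: np.ndarray,
    land_use: np.ndarray,
    abz: np.ndarray,
    params: list[dict],
    weather: float,
    k_max: float,
    cell_size_m: float,
    extinction_threshold: float = 1.0,
    uptake_form: str = "printed",
) -> np.ndarray:
    """One synchronous growth step, computed cell by cell and type by type.

    ``params[j]`` needs keys: r, c, period ('first'/'second'/'both'),
    forage_suit (6,), nest_suit (6,), disp_mean, trans_res, trans_nest, b.
    """
    S, R, C = N.shape

    # foraging abundance: each population spread over its disk
    F = np.zeros_like(N)
    for j in range(S):
        radius = params[j]["disp_mean"] / cell_size_m
        for r in range(R):
            for c in range(C):
                if N[j, r, c] > 0:
                    for rr in range(R):
                        for cc in range(C):
                            if _in_range(r, c, rr, cc, radius):
                                F[j, rr, cc] += N[j, r, c]

    def beta_and_ntotal(A, j, r, c, present):
        c_total = sum(params[i]["c"] for i in range(S) if present[i])
        beta, n_total = 0.0, 0.0
        for i in range(S):
            if not _overlap(params[i]["period"], params[j]["period"]):
                continue
            n_total += A[i, r, c]
            if i != j:
                term = 1.0
                if c_total > 0:
                    term += (params[j]["c"] - params[i]["c"]) / c_total
                beta += term * A[i, r, c]
        return max(beta, 0.0), n_total

    # per-cell competition-dependent resource uptake
    uptake = np.zeros_like(N)
    for j in range(S):
        for r in range(R):
            for c in range(C):
                present = [(F[i, r, c] > 0) or (N[i, r, c] > 0) for i in range(S)]
                beta, n_total = beta_and_ntotal(F, j, r, c, present)
                suit = params[j]["forage_suit"][int(land_use[r, c])]
                if abz[r, c]:
                    suit += params[j]["trans_res"]
                if uptake_form == "printed":
                    ratio = (beta + F[j, r, c]) / n_total if n_total > 0 else 1.0
                else:
                    denom = beta + F[j, r, c]
                    ratio = n_total / denom if denom > 0 else 1.0
                uptake[j, r, c] = ratio * suit

    out = np.zeros_like(N)
    for j in range(S):
        radius = params[j]["disp_mean"] / cell_size_m
        for r in range(R):
            for c in range(C):
                if N[j, r, c] <= 0:
                    continue
                cells = [
                    (rr, cc)
                    for rr in range(R)
                    for cc in range(C)
                    if _in_range(r, c, rr, cc, radius)
                ]
                mean_uptake = sum(uptake[j, rr, cc] for rr, cc in cells) / len(cells)
                present = [N[i, r, c] > 0 for i in range(S)]
                beta_nest, _ = beta_and_ntotal(N, j, r, c, present)
                suit = params[j]["nest_suit"][int(land_use[r, c])]
                if abz[r, c]:
                    suit += params[j]["trans_nest"]
                K = k_max * suit
                if K <= 0:
                    continue
                rr_ = params[j]["r"]
                dens = (N[j, r, c] + beta_nest) / K
                n_next = (
                    N[j, r, c] * rr_ * weather * mean_uptake
                    / (1.0 + (rr_ - 1.0) * dens ** params[j]["b"])
                )
                out[j, r, c] = n_next if n_next >= extinction_threshold else 0.0
    return out


def params_from_community(community) -> list[dict]:
    """Extract the oracle's parameter dicts from a community object."""
    out = []
    for profile, p in zip(community.profiles, community.parameters):
        out.append(
            {
                "r": p.r,
                "c": p.c,
                "period": profile.flying_period.value,
                "forage_suit": list(p.forage_suitability),
                "nest_suit": list(p.nest_suitability),
                "disp_mean": p.disp_mean,
                "trans_res": p.trans_effect_res,
                "trans_nest": p.trans_effect_nest,
                "b": p.b,
            }
        )
    return out
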