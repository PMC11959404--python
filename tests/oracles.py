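"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit Python loops, no shared
code with the package) so it can serve as a second, independent route to
the same quantities.
"""

from __future__ import annotations

import math

SCORES = ("score_fa", "score_ta", "score_fp", "score_tp")


def naive_balanced_components(table):
    """Two-way crossed EMS components by direct summation.

    Returns (sigma_t, sigma_p, sigma_tp) as nested 4x4 lists, raw
    (untruncated).  Requires a fully crossed table.
    """
    cells = {}
    for row in table.itertuples(index=False):
        cells[(row.trainee_id, row.procedure_id)] = [
            getattr(row, c) for c in SCORES
        ]
    trainees = sorted({t for t, _ in cells})
    procedures = sorted({p for _, p in cells})
    n_t, n_p = len(trainees), len(procedures)
    assert len(cells) == n_t * n_p, "oracle requires full crossing"

    grand = [0.0] * 4
    for val in cells.values():
        for u in range(4):
            grand[u] += val[u]
    grand = [g / (n_t * n_p) for g in grand]

    t_mean = {
        t: [
            sum(cells[(t, p)][u] for p in procedures) / n_p - grand[u]
            for u in range(4)
        ]
        for t in trainees
    }
    p_mean = {
        p: [
            sum(cells[(t, p)][u] for t in trainees) / n_t - grand[u]
            for u in range(4)
        ]
        for p in procedures
    }

    ms_t = [[0.0] * 4 for _ in range(4)]
    ms_p = [[0.0] * 4 for _ in range(4)]
    ms_tp = [[0.0] * 4 for _ in range(4)]
    for u in range(4):
        for v in range(4):
            ms_t[u][v] = (
                n_p
                * sum(t_mean[t][u] * t_mean[t][v] for t in trainees)
                / (n_t - 1)
            )
            ms_p[u][v] = (
                n_t
                * sum(p_mean[p][u] * p_mean[p][v] for p in procedures)
                / (n_p - 1)
            )
            acc = 0.0
            for t in trainees:
                for p in procedures:
                    ru = cells[(t, p)][u] - grand[u] - t_mean[t][u] - p_mean[p][u]
                    rv = cells[(t, p)][v] - grand[v] - t_mean[t][v] - p_mean[p][v]
                    acc += ru * rv
            ms_tp[u][v] = acc / ((n_t - 1) * (n_p - 1))

    sigma_tp = [[ms_tp[u][v] for v in range(4)] for u in range(4)]
    sigma_t = [
        [(ms_t[u][v] - ms_tp[u][v]) / n_p for v in range(4)] for u in range(4)
    ]
    sigma_p = [
        [(ms_p[u][v] - ms_tp[u][v]) / n_t for v in range(4)] for u in range(4)
    ]
    return sigma_t, sigma_p, sigma_tp


def phi_closed_form(tau, error_per_procedure, n):
    """Index of dependability from the scalar closed form."""
    return tau / (tau + error_per_procedure / n)


def min_procedures_scan(tau, error_per_procedure, threshold, n_max):
    """Linear scan for the smallest n with Phi(n) >= threshold.

    Uses a 1e-9 relative slack so that a binary threshold like 0.8 counts
    Phi exactly 0.8 as attained (mirrors the implementation contract).
    """
    for n in range(1, n_max + 1):
        if phi_closed_form(tau, error_per_procedure, n) >= threshold * (1 - 1e-9):
            return n
    return None


def min_procedures_closed_form(tau, error_per_procedure, threshold):
    x = threshold / (1 - threshold) * error_per_procedure / tau
    return max(1, math.ceil(x * (1 - 1e-9)))
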