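"""Independent reference implementations used only to cross-check qebss.

Everything here is written directly from the physics: closed-form
Lorentzian spectral densities in the Redfield rate expressions, and plain
double/triple-loop estimators for correlation functions and distance maps.
Nothing imports the implementation under test.
"""

import math

import numpy as np

# Constants restated independently (CODATA / SI).
_GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
_GAMMA_N = -2.71261804e7
_MU0 = 4.0e-7 * math.pi
_HBAR = 1.054571817e-34


def closed_form_redfield(tau_s, field_mhz, delta_sigma_ppm=-160.0,
                         r_nh_nm=0.101, dipolar_only=False):
    """(T1, T2, hetNOE) for a single-Lorentzian spectral density.

    J(w) = 2 tau / (1 + (w tau)^2); dipolar (1H-15N) + 15N CSA mechanisms;
    cross-relaxation sigma = (d^2/20) (6 J(wH+wN) - J(wH-wN)).
    """
    d = _MU0 * _HBAR * _GAMMA_H * _GAMMA_N / (
        4.0 * math.pi * (r_nh_nm * 1e-9) ** 3
    )
    c = 0.0 if dipolar_only else delta_sigma_ppm * 1e-6
    w_h = 2.0 * math.pi * field_mhz * 1e6
    w_n = w_h * _GAMMA_N / _GAMMA_H

    def j(w):
        return 2.0 * tau_s / (1.0 + (abs(w) * tau_s) ** 2)

    r1 = d * d / 20.0 * (j(w_h - w_n) + 3.0 * j(w_n) + 6.0 * j(w_h + w_n)) \
        + (c * w_n) ** 2 / 15.0 * j(w_n)
    r2 = 0.5 * d * d / 20.0 * (
        4.0 * j(0.0) + j(w_h - w_n) + 3.0 * j(w_n) + 6.0 * j(w_h)
        + 6.0 * j(w_h + w_n)
    ) + (c * w_n) ** 2 / 90.0 * (4.0 * j(0.0) + 3.0 * j(w_n))
    sigma = d * d / 20.0 * (6.0 * j(w_h + w_n) - j(w_h - w_n))
    t1 = 1.0 / r1
    return t1, 1.0 / r2, 1.0 + sigma * _GAMMA_H * t1 / _GAMMA_N


def brute_force_p2_acf(vectors, n_lags):
    """P2 autocorrelation by the explicit double loop over origin pairs."""
    v = np.asarray(vectors, dtype=float)
    n = v.shape[0]
    g = np.zeros(n_lags)
    for lag in range(n_lags):
        vals = []
        for t0 in range(n - lag):
            c = float(np.dot(v[t0], v[t0 + lag]))
            vals.append(1.5 * c * c - 0.5)
        g[lag] = np.mean(vals)
    return g


def brute_force_mindist(frames, residue_groups):
    """Average minimum inter-residue distance by the all-pairs triple loop."""
    frames = np.asarray(frames, dtype=float)
    n_res = len(residue_groups)
    acc = np.zeros((n_res, n_res))
    for frame in frames:
        for i in range(n_res):
            for j in range(n_res):
                if i == j:
                    continue
                best = math.inf
                for a in residue_groups[i]:
                    for b in residue_groups[j]:
                        d = float(np.linalg.norm(frame[a] - frame[b]))
                        best = min(best, d)
                acc[i, j] += best
    return acc / frames.shape[0]
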