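"""Independently coded scalar reference Monte Carlo for engine validation.

A deliberately simple, slow, pure-Python transport loop for plane-parallel
layer stacks, kept free of the optimized engine's machinery: it uses the
standard-library Mersenne Twister, re-samples a fresh physical free path
after every boundary crossing (statistically equivalent to carrying the
dimensionless remainder, by the memoryless property of the exponential), and
tallies with plain floats.  It exists solely as a cross-check oracle for the
compiled engines on small photon counts; it shares no transport code with
them.
"""

from __future__ import annotations

import math
import random

__all__ = ["reference_slab"]

_WEIGHT_MIN = 1e-4
_SURVIVE = 0.1


def _fresnel_unpolarized(n1: float, n2: float, cos_i: float) -> tuple[float, float]:
    if n1 == n2:
        return 0.0, cos_i
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 * sin_i / n2
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    if cos_i > 0.99999:
        r = ((n2 - n1) / (n2 + n1)) ** 2
        return r, cos_t
    # explicit s/p average (different formulation from the engine's)
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    return 0.5 * (rs + rp), cos_t


def reference_slab(
    layers: list[tuple[float, float, float, float, float]],
    n_photons: int,
    seed: int,
    n_above: float = 1.0,
    n_below: float = 1.0,
) -> dict:
    """Transport photons through layers of (mu_a, mu_s, g, n, thickness_mm).

    Returns a dict with Rd (diffuse), Rs (specular, analytic), Tt, A and
    binomial-style standard errors for Rd and Tt.
    """
    rng = random.Random(seed)
    zb = [0.0]
    for lay in layers:
        zb.append(zb[-1] + lay[4])
    n_layers = len(layers)

    # analytic specular term, two-interface if the top layer is clear
    n1 = layers[0][3]
    r1 = ((n_above - n1) / (n_above + n1)) ** 2
    if layers[0][0] == 0.0 and layers[0][1] == 0.0 and n_layers > 1:
        n2 = layers[1][3]
        r2 = ((n1 - n2) / (n1 + n2)) ** 2
        rs = r1 + (1.0 - r1) ** 2 * r2 / (1.0 - r1 * r2)
        start = 1
    else:
        rs = r1
        start = 0

    rd = tt = aa = 0.0
    rd_sq = tt_sq = 0.0

    for _ in range(n_photons):
        z = zb[start]
        ux, uy, uz = 0.0, 0.0, 1.0
        w = 1.0 - rs
        lay = start
        alive = True
        while alive:
            mu_a, mu_s, g, n_cur, _t = layers[lay]
            mu_t = mu_a + mu_s
            # free path (fresh draw each leg; memoryless)
            path = -math.log(max(rng.random(), 1e-300)) / mu_t if mu_t > 0 else math.inf
            if uz > 0:
                d_bound = (zb[lay + 1] - z) / uz
            elif uz < 0:
                d_bound = (zb[lay] - z) / uz
            else:
                d_bound = math.inf
            if path < d_bound:
                z += path * uz
                dw = w * mu_a / mu_t
                aa += dw
                w -= dw
                if mu_s == 0.0 or w <= 0.0:
                    aa += w
                    break
                # Henyey-Greenstein deflection
                if g == 0.0:
                    ct = 2.0 * rng.random() - 1.0
                else:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * rng.random())
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                ct = max(-1.0, min(1.0, ct))
                st_ = math.sqrt(1.0 - ct * ct)
                phi = 2.0 * math.pi * rng.random()
                cp, sp = math.cos(phi), math.sin(phi)
                if abs(uz) > 0.99999:
                    ux, uy, uz = st_ * cp, st_ * sp, ct * (1.0 if uz > 0 else -1.0)
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    ux, uy, uz = (
                        st_ * (ux * uz * cp - uy * sp) / den + ux * ct,
                        st_ * (uy * uz * cp + ux * sp) / den + uy * ct,
                        -st_ * cp * den + uz * ct,
                    )
                if w < _WEIGHT_MIN:
                    if rng.random() < _SURVIVE:
                        aa -= w * (1.0 / _SURVIVE - 1.0)
                        w /= _SURVIVE
                    else:
                        aa += w
                        break
            else:
                if math.isinf(d_bound):
                    aa += w
                    break
                down = uz > 0
                z = zb[lay + 1] if down else zb[lay]
                nxt = lay + 1 if down else lay - 1
                if down:
                    n_next = n_below if nxt == n_layers else layers[nxt][3]
                else:
                    n_next = n_above if nxt < 0 else layers[nxt][3]
                refl, cos_t = _fresnel_unpolarized(n_cur, n_next, abs(uz))
                if rng.random() < refl:
                    uz = -uz
                elif (down and nxt == n_layers) or (not down and nxt < 0):
                    if down:
                        tt += w
                        tt_sq += w * w
                    else:
                        rd += w
                        rd_sq += w * w
                    break
                else:
                    ratio = n_cur / n_next
                    ux *= ratio
                    uy *= ratio
                    uz = cos_t if down else -cos_t
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux, uy, uz = ux / norm, uy / norm, uz / norm
                    lay = nxt

    def se(total, sq):
        mean = total / n_photons
        var = max(0.0, sq / n_photons - mean * mean)
        return math.sqrt(var / n_photons)

    return {
        "rd": rd / n_photons,
        "rs": rs,
        "tt": tt / n_photons,
        "a": aa / n_photons,
        "se_rd": se(rd, rd_sq),
        "se_tt": se(tt, tt_sq),
    }
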