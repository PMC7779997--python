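"""Numba-compiled inner loops: photon transport and history post-processing.

Transport is scattering-only: absorption is applied afterwards through the
pathlength weights of the layered autocorrelation model, so one photon
history serves any absorption setting.  Scattering is isotropic at the
reduced rate mu_s' (similarity relation) by default; each scattering event
adds ``1 - cos(theta)`` to the momentum-transfer tally of the layer it
occurs in, so the expected per-event contribution is 1.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TWO_PI = 2.0 * math.pi


@njit(cache=True, inline="always")
def _fresnel_reflectance(ci: float, n1: float, n2: float) -> float:
    """Unpolarised Fresnel reflectance for cosine of incidence ``ci`` (n1 -> n2)."""
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n1 / n2 * si
    if st >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st * st)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def transport_slab(n_photons, seed, mus, dz, n_fine, z_max, r_max, n_tissue,
                   n_external, max_path, ann_lo, ann_hi,
                   L_out, Y_out, det_out):
    """Pencil-beam photon random walk in a layered slab.

    The beam enters at the origin along +z; layer ``i`` occupies
    ``[i*dz, (i+1)*dz)`` for i < n_fine and the terminal medium (index
    ``n_fine``) spans down to ``z_max`` where it is absorbed.  Photons
    escaping the top surface through the Fresnel boundary inside one of the
    detector annuli are recorded with their per-layer L and Y.

    Returns ``(count, overflow)``: photons recorded and detections dropped
    because the output buffers were full.
    """
    np.random.seed(seed)
    cap = det_out.shape[0]
    n_lay = n_fine + 1
    n_ann = ann_lo.shape[0]
    Lbuf = np.zeros(n_lay)
    Ybuf = np.zeros(n_lay)
    count = 0
    overflow = 0
    r_max2 = r_max * r_max
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        for i in range(n_lay):
            Lbuf[i] = 0.0
            Ybuf[i] = 0.0
        layer = 0
        path = 0.0
        detected = -1
        alive = True
        while alive:
            s = -math.log(np.random.random() + 1e-300) / mus[layer]
            # distance to the layer boundary along the current direction
            if uz > 0.0:
                zb = z_max if layer == n_fine else (layer + 1) * dz
                db = (zb - z) / uz
            elif uz < 0.0:
                zb = layer * dz
                db = (zb - z) / uz
            else:
                db = 1e30
            if s < db:
                x += ux * s
                y += uy * s
                z += uz * s
                Lbuf[layer] += s
                path += s
                # isotropic scattering: new direction uniform on the sphere
                cost = 2.0 * np.random.random() - 1.0
                sint = math.sqrt(1.0 - cost * cost)
                phi = _TWO_PI * np.random.random()
                nx = sint * math.cos(phi)
                ny = sint * math.sin(phi)
                nz = cost
                Ybuf[layer] += 1.0 - (ux * nx + uy * ny + uz * nz)
                ux = nx
                uy = ny
                uz = nz
            else:
                x += ux * db
                y += uy * db
                Lbuf[layer] += db
                path += db
                if uz < 0.0 and layer == 0:
                    z = 0.0
                    ci = -uz
                    if np.random.random() < _fresnel_reflectance(ci, n_tissue, n_external):
                        uz = -uz
                    else:
                        r = math.sqrt(x * x + y * y)
                        for k in range(n_ann):
                            if ann_lo[k] <= r <= ann_hi[k]:
                                detected = k
                                break
                        alive = False
                elif uz > 0.0 and layer == n_fine:
                    alive = False  # absorbed at the bottom of the domain
                else:
                    z = zb
                    layer = layer + 1 if uz > 0.0 else layer - 1
            if path > max_path or x * x + y * y > r_max2:
                alive = False
        if detected >= 0:
            if count < cap:
                for i in range(n_lay):
                    L_out[count, i] = Lbuf[i]
                    Y_out[count, i] = Ybuf[i]
                det_out[count] = detected
                count += 1
            else:
                overflow += 1
    return count, overflow


@njit(cache=True, fastmath=True)
def transport_shell(n_photons, seed, mus, dz, n_fine, z_max, outer_radius,
                    n_tissue, n_external, max_path, ann_lo, ann_hi,
                    L_out, Y_out, det_out):
    """Photon random walk in concentric spherical shells (curved surrogate).

    The sphere is centred at the origin with outer radius ``outer_radius``;
    the source enters at the +z pole pointing inward.  Fine layer ``i``
    occupies radii ``(outer_radius - (i+1)*dz, outer_radius - i*dz]`` and the
    terminal medium continues to depth ``z_max`` where photons are absorbed.
    Detector annuli are expressed as arc-length bands on the sphere surface
    measured from the source point.
    """
    np.random.seed(seed)
    cap = det_out.shape[0]
    n_lay = n_fine + 1
    n_ann = ann_lo.shape[0]
    Lbuf = np.zeros(n_lay)
    Ybuf = np.zeros(n_lay)
    count = 0
    overflow = 0
    r_kill = outer_radius - z_max
    if r_kill < 0.0:
        r_kill = 0.0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = outer_radius
        ux = 0.0
        uy = 0.0
        uz = -1.0
        for i in range(n_lay):
            Lbuf[i] = 0.0
            Ybuf[i] = 0.0
        layer = 0
        path = 0.0
        detected = -1
        alive = True
        while alive:
            s = -math.log(np.random.random() + 1e-300) / mus[layer]
            r2 = x * x + y * y + z * z
            b = x * ux + y * uy + z * uz
            # inner boundary of the current layer (terminal ends at r_kill)
            r_in = r_kill if layer == n_fine else outer_radius - (layer + 1) * dz
            if r_in < 0.0:
                r_in = 0.0
            hit_inner = False
            db = 1e30
            if r_in > 0.0:
                disc = b * b - (r2 - r_in * r_in)
                if disc > 0.0:
                    t_in = -b - math.sqrt(disc)
                    if t_in > 1e-12:
                        db = t_in
                        hit_inner = True
            if not hit_inner:
                r_out = outer_radius if layer == 0 else outer_radius - layer * dz
                disc = b * b - (r2 - r_out * r_out)
                if disc < 0.0:
                    disc = 0.0
                db = -b + math.sqrt(disc)
                if db < 1e-12:
                    db = 1e-12
            if s < db:
                x += ux * s
                y += uy * s
                z += uz * s
                Lbuf[layer] += s
                path += s
                cost = 2.0 * np.random.random() - 1.0
                sint = math.sqrt(1.0 - cost * cost)
                phi = _TWO_PI * np.random.random()
                nx = sint * math.cos(phi)
                ny = sint * math.sin(phi)
                nz = cost
                Ybuf[layer] += 1.0 - (ux * nx + uy * ny + uz * nz)
                ux = nx
                uy = ny
                uz = nz
            else:
                x += ux * db
                y += uy * db
                z += uz * db
                Lbuf[layer] += db
                path += db
                if hit_inner:
                    if layer == n_fine:
                        alive = False  # absorbed at the inner kill radius
                    else:
                        layer += 1
                elif layer == 0:
                    # outer surface: Fresnel escape or internal reflection
                    rr = math.sqrt(x * x + y * y + z * z)
                    nxs = x / rr
                    nys = y / rr
                    nzs = z / rr
                    ci = ux * nxs + uy * nys + uz * nzs
                    if ci < 0.0:
                        ci = -ci
                    if np.random.random() < _fresnel_reflectance(ci, n_tissue, n_external):
                        dot = ux * nxs + uy * nys + uz * nzs
                        ux -= 2.0 * dot * nxs
                        uy -= 2.0 * dot * nys
                        uz -= 2.0 * dot * nzs
                        # pull back inside to avoid re-crossing due to round-off
                        x = nxs * (outer_radius - 1e-9)
                        y = nys * (outer_radius - 1e-9)
                        z = nzs * (outer_radius - 1e-9)
                    else:
                        cang = nzs
                        if cang > 1.0:
                            cang = 1.0
                        elif cang < -1.0:
                            cang = -1.0
                        arc = outer_radius * math.acos(cang)
                        for k in range(n_ann):
                            if ann_lo[k] <= arc <= ann_hi[k]:
                                detected = k
                                break
                        alive = False
                else:
                    layer -= 1
            if path > max_path:
                alive = False
        if detected >= 0:
            if count < cap:
                for i in range(n_lay):
                    L_out[count, i] = Lbuf[i]
                    Y_out[count, i] = Ybuf[i]
                det_out[count] = detected
                count += 1
            else:
                overflow += 1
    return count, overflow


@njit(cache=True, fastmath=True)
def g1_eval(w, rate_fixed, y_brain, tau, brain_bfi_rate):
    """Normalised G1(tau) = sum_n w_n exp(-(rate_fixed_n + y_brain_n * B) tau).

    ``w`` are the static absorption weights, ``rate_fixed`` the decay rates
    contributed by the constrained layers, ``y_brain`` the brain-layer
    momentum-transfer rate coefficients and ``brain_bfi_rate`` the trial
    brain BFi (already multiplied into rate units by the caller).
    """
    nt = tau.size
    out = np.zeros(nt)
    wsum = 0.0
    for n in range(w.size):
        wn = w[n]
        wsum += wn
        r = rate_fixed[n] + y_brain[n] * brain_bfi_rate
        for t in range(nt):
            out[t] += wn * math.exp(-r * tau[t])
    for t in range(nt):
        out[t] /= wsum
    return out
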