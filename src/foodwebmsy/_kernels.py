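"""Compiled inner loops for the biomass integrator.

Mirrors ``Simulator.derivatives`` exactly; the Python implementation stays
the reference path for single evaluations and the Jacobian, this one does
the long runs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _flux_sums(B, prey_idx, pred_idx, link_v, link_D, link_vuser, vm,
               imp_rate, Qin, Qout):
    n = B.shape[0]
    for i in range(n):
        Qin[i] = imp_rate[i] * B[i]
        Qout[i] = 0.0
    for l in range(prey_idx.shape[0]):
        s = vm[l] * link_vuser[l]
        if s < 1.0:
            s = 1.0
        s = s / link_vuser[l]
        Bp = B[prey_idx[l]]
        Bq = B[pred_idx[l]]
        den = s * link_D[l] + Bq
        if den > 0.0:
            fl = s * link_v[l] * Bp * Bq / den
        else:
            fl = 0.0
        Qin[pred_idx[l]] += fl
        Qout[prey_idx[l]] += fl


@njit(cache=True)
def _deriv(B, F, pb, vm, ov_mask,
           prey_idx, pred_idx, link_v, link_D, link_vuser,
           imp_rate, g, MO, PB0, prod_h, GS, I, e_rate,
           is_consumer, is_producer, is_detritus, frozen, qss,
           det_idx, det_share, det_export, logistic,
           dB, Qin, Qout):
    n = B.shape[0]
    _flux_sums(B, prey_idx, pred_idx, link_v, link_D, link_vuser, vm,
               imp_rate, Qin, Qout)
    inflow = 0.0
    for i in range(n):
        if is_producer[i]:
            if logistic:
                pp = PB0[i] * B[i] * (2.0 - prod_h[i] * B[i])
                if pp < 0.0:
                    pp = 0.0
            else:
                pp = 2.0 * PB0[i] * B[i] / (1.0 + prod_h[i] * B[i])
            prod = pb[i] * pp
        else:
            prod = pb[i] * g[i] * Qin[i]
        MOe = pb[i] * MO[i]
        dB[i] = prod - Qout[i] + I[i] - (MOe + F[i] + e_rate[i]) * B[i]
        if not is_detritus[i]:
            inflow += MOe * B[i]
            if is_consumer[i]:
                inflow += GS[i] * Qin[i]
    for p in range(det_idx.shape[0]):
        d = det_idx[p]
        dB[d] = inflow * det_share[p] - Qout[d] - det_export[d] * B[d]
        if qss[d]:
            dB[d] = 0.0
    for i in range(n):
        if frozen[i] or ov_mask[i]:
            dB[i] = 0.0


@njit(cache=True)
def _qss_snap(B, pb, vm,
              prey_idx, pred_idx, link_v, link_D, link_vuser,
              imp_rate, MO, GS, is_consumer, is_detritus, frozen,
              det_idx, det_share, det_export, qss, Qin, Qout):
    if det_idx.shape[0] == 0:
        return
    any_qss = False
    for p in range(det_idx.shape[0]):
        d = det_idx[p]
        if qss[d] and not frozen[d]:
            any_qss = True
    if not any_qss:
        return
    n = B.shape[0]
    for _ in range(2):
        _flux_sums(B, prey_idx, pred_idx, link_v, link_D, link_vuser, vm,
                   imp_rate, Qin, Qout)
        inflow = 0.0
        for i in range(n):
            if not is_detritus[i]:
                inflow += pb[i] * MO[i] * B[i]
                if is_consumer[i]:
                    inflow += GS[i] * Qin[i]
        for p in range(det_idx.shape[0]):
            d = det_idx[p]
            if qss[d] and not frozen[d] and B[d] > 0.0:
                k_rate = Qout[d] / B[d] + det_export[d]
                if k_rate > 1e-12:
                    B[d] = inflow * det_share[p] / k_rate


@njit(cache=True)
def rk4_run(B_init, n_steps, n_sub, dt, year_mid, year_next,
            F_years, pb_years, vm_years, ov_vals, ov_mask,
            prey_idx, pred_idx, link_v, link_D, link_vuser,
            imp_rate, g, MO, PB0, prod_h, GS, I, e_rate,
            is_consumer, is_producer, is_detritus, frozen, qss,
            det_idx, det_share, det_export, logistic,
            B0, floor, bio_out):
    """Fixed-step RK4 over the full horizon.

    Returns 0 on success, or (step index + 1) of the first non-finite
    state.  ``bio_out`` must be (n_steps + 1, n).
    """
    n = B_init.shape[0]
    B = B_init.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    Bt = np.empty(n)
    Qin = np.empty(n)
    Qout = np.empty(n)

    # initial override at year 0
    for i in range(n):
        if ov_mask[0, i]:
            B[i] = ov_vals[0, i]
        bio_out[0, i] = B[i]

    dt_s = dt / n_sub
    for k in range(n_steps):
        yr = year_mid[k]
        F = F_years[yr]
        pb = pb_years[yr]
        vm = vm_years[yr]
        ovm = ov_mask[yr]

        for _ in range(n_sub):
            _deriv(B, F, pb, vm, ovm, prey_idx, pred_idx, link_v, link_D,
                   link_vuser, imp_rate, g, MO, PB0, prod_h, GS, I, e_rate,
                   is_consumer, is_producer, is_detritus, frozen, qss,
                   det_idx, det_share, det_export, logistic, k1, Qin, Qout)
            for i in range(n):
                Bt[i] = B[i] + 0.5 * dt_s * k1[i]
                if Bt[i] < 0.0:
                    Bt[i] = 0.0
            _deriv(Bt, F, pb, vm, ovm, prey_idx, pred_idx, link_v, link_D,
                   link_vuser, imp_rate, g, MO, PB0, prod_h, GS, I, e_rate,
                   is_consumer, is_producer, is_detritus, frozen, qss,
                   det_idx, det_share, det_export, logistic, k2, Qin, Qout)
            for i in range(n):
                Bt[i] = B[i] + 0.5 * dt_s * k2[i]
                if Bt[i] < 0.0:
                    Bt[i] = 0.0
            _deriv(Bt, F, pb, vm, ovm, prey_idx, pred_idx, link_v, link_D,
                   link_vuser, imp_rate, g, MO, PB0, prod_h, GS, I, e_rate,
                   is_consumer, is_producer, is_detritus, frozen, qss,
                   det_idx, det_share, det_export, logistic, k3, Qin, Qout)
            for i in range(n):
                Bt[i] = B[i] + dt_s * k3[i]
                if Bt[i] < 0.0:
                    Bt[i] = 0.0
            _deriv(Bt, F, pb, vm, ovm, prey_idx, pred_idx, link_v, link_D,
                   link_vuser, imp_rate, g, MO, PB0, prod_h, GS, I, e_rate,
                   is_consumer, is_producer, is_detritus, frozen, qss,
                   det_idx, det_share, det_export, logistic, k4, Qin, Qout)
            for i in range(n):
                B[i] = B[i] + (dt_s / 6.0) * (k1[i] + 2.0 * k2[i]
                                              + 2.0 * k3[i] + k4[i])
                if frozen[i]:
                    B[i] = B0[i]
                elif B[i] < floor[i]:
                    B[i] = floor[i]
            _qss_snap(B, pb, vm, prey_idx, pred_idx, link_v, link_D,
                      link_vuser, imp_rate, MO, GS, is_consumer, is_detritus,
                      frozen, det_idx, det_share, det_export, qss, Qin, Qout)

        bad = False
        for i in range(n):
            if not np.isfinite(B[i]):
                bad = True
        if bad:
            for i in range(n):
                bio_out[k + 1, i] = B[i]
            return k + 1

        yrn = year_next[k]
        for i in range(n):
            if ov_mask[yrn, i]:
                B[i] = ov_vals[yrn, i]
            bio_out[k + 1, i] = B[i]
    return 0
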