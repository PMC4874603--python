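"""Compiled network integration core.

A single numba kernel advances the whole network with the 2nd-order
Runge-Kutta (midpoint) scheme at a maximum step of ``dt_max``.  Synaptic
conductances are linear filters (one rising and one decaying exponential
accumulator per receptor per neuron) and are propagated with their exact
exponential solution; delayed spike deliveries live in a binary min-heap.

Two stepping modes:

* ``event_split=True``  — every pending delivery terminates the step
  exactly at the event time (spikes, synaptic and external events are
  exactly timed; the step count grows with the event count).
* ``event_split=False`` — deliveries inside a step are injected into the
  conductance accumulators analytically at their exact arrival times
  (kernels start at zero amplitude, so the membrane step, which does not
  split, sees an O(h) lag only in the first <=0.05 ms of each kernel rise).

Spike threshold crossings are located by linear interpolation inside the
step; the reset is applied at the step end and delayed deliveries are
scheduled at t_cross + tau_D.  Minimum delay (0.1 ms) exceeds the maximum
step (0.05 ms), so deliveries never land inside the step that emits them.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1

_EPS = 1e-9


@njit(cache=True, inline="always")
def _heap_push(ht, hi, ha, n, t, idx, amp):
    ht[n] = t
    hi[n] = idx
    ha[n] = amp
    i = n
    while i > 0:
        par = (i - 1) >> 1
        if ht[par] <= ht[i]:
            break
        ht[par], ht[i] = ht[i], ht[par]
        hi[par], hi[i] = hi[i], hi[par]
        ha[par], ha[i] = ha[i], ha[par]
        i = par
    return n + 1


@njit(cache=True, inline="always")
def _heap_pop(ht, hi, ha, n):
    t0, i0, a0 = ht[0], hi[0], ha[0]
    n -= 1
    ht[0], hi[0], ha[0] = ht[n], hi[n], ha[n]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        sm = i
        if l < n and ht[l] < ht[sm]:
            sm = l
        if r < n and ht[r] < ht[sm]:
            sm = r
        if sm == i:
            break
        ht[sm], ht[i] = ht[i], ht[sm]
        hi[sm], hi[i] = hi[i], hi[sm]
        ha[sm], ha[i] = ha[i], ha[sm]
        i = sm
    return t0, i0, a0, n


@njit(cache=True)
def run_core(
    # neuron parameters
    C, gL, EL, DT, tauw, b_inc, Vr, Vth, Vup, Ibg,
    # synapses, CSR-grouped by presynaptic neuron
    out_ptr, out_idx, syn_post, syn_gA, syn_gG, syn_gN, syn_delay,
    syn_U, syn_taurec, syn_taufac, syn_pfail,
    # precomputed external deliveries (stimulus volleys)
    ext_t, ext_post, ext_gA, ext_gG, ext_gN,
    # receptor kinetics
    tau_onA, tau_offA, tau_onG, tau_offG, tau_onN, tau_offN,
    normA, normG, normN, ErevA, ErevG, ErevN,
    # run control
    T, dt_max, seed, sample_dt, rec_ids, event_split, record_v,
    V0, w0,
):
    np.random.seed(seed)
    N = C.shape[0]
    M = syn_post.shape[0]

    V = V0.copy()
    w = w0.copy()
    xAon = np.zeros(N); xAoff = np.zeros(N)
    xGon = np.zeros(N); xGoff = np.zeros(N)
    xNon = np.zeros(N); xNoff = np.zeros(N)
    # midpoint conductance buffers
    mAon = np.zeros(N); mAoff = np.zeros(N)
    mGon = np.zeros(N); mGoff = np.zeros(N)
    mNon = np.zeros(N); mNoff = np.zeros(N)

    # short-term plasticity state per synapse
    stp_u = np.zeros(M)
    stp_R = np.ones(M)
    stp_tl = np.full(M, -1.0e30)

    taum = C / gL
    rband = np.minimum(taum / tauw, 0.95)

    n_samples = int(round(T / sample_dt)) + 1
    n_rec = rec_ids.shape[0] if record_v else 0
    Vrec = np.zeros((n_rec, n_samples), dtype=np.float32)
    lfp = np.zeros(n_samples)
    isyn_int = np.zeros(N)

    # event heap
    cap = 4 * (ext_t.shape[0] + 1024)
    ht = np.empty(cap)
    hi = np.empty(cap, dtype=np.int64)
    ha = np.empty(cap)
    hn = 0
    for k in range(ext_t.shape[0]):
        if hn >= cap:
            cap *= 2
            ht2 = np.empty(cap); ht2[:hn] = ht[:hn]; ht = ht2
            hi2 = np.empty(cap, dtype=np.int64); hi2[:hn] = hi[:hn]; hi = hi2
            ha2 = np.empty(cap); ha2[:hn] = ha[:hn]; ha = ha2
        hn = _heap_push(ht, hi, ha, hn, ext_t[k], -k - 1, 0.0)

    # recorded spikes
    sp_cap = 1 << 14
    sp_nrn = np.empty(sp_cap, dtype=np.int64)
    sp_t = np.empty(sp_cap)
    sp_n = 0

    # step-local buffers
    emit = np.empty(N, dtype=np.int64)
    emit_t = np.empty(N)
    evb_cap = 1 << 12
    evb_td = np.empty(evb_cap)
    evb_post = np.empty(evb_cap, dtype=np.int64)
    evb_gA = np.empty(evb_cap)
    evb_gG = np.empty(evb_cap)
    evb_gN = np.empty(evb_cap)

    # t = 0 sample
    if record_v:
        for j in range(n_rec):
            Vrec[j, 0] = V[rec_ids[j]]
    lfp[0] = 0.0

    t = 0.0
    next_sample = 1
    while t < T - _EPS:
        # deliveries due exactly now (step boundaries; all events in split mode)
        while hn > 0 and ht[0] <= t + _EPS:
            td, idx, amp, hn = _heap_pop(ht, hi, ha, hn)
            if idx >= 0:
                p = syn_post[idx]
                dgA = amp * syn_gA[idx] * normA
                dgG = amp * syn_gG[idx] * normG
                dgN = amp * syn_gN[idx] * normN
            else:
                k = -idx - 1
                p = ext_post[k]
                dgA = ext_gA[k] * normA
                dgG = ext_gG[k] * normG
                dgN = ext_gN[k] * normN
            xAon[p] += dgA; xAoff[p] += dgA
            xGon[p] += dgG; xGoff[p] += dgG
            xNon[p] += dgN; xNoff[p] += dgN

        t_next = t + dt_max
        if t_next > T:
            t_next = T
        ts = next_sample * sample_dt
        if next_sample < n_samples and ts < t_next - _EPS:
            t_next = ts
        if event_split and hn > 0 and ht[0] < t_next - _EPS:
            t_next = ht[0]
        h = t_next - t
        if h < _EPS:
            # degenerate step (boundary already reached): only bookkeeping
            t = t_next
            if next_sample < n_samples and t >= next_sample * sample_dt - _EPS:
                if record_v:
                    for j in range(n_rec):
                        Vrec[j, next_sample] = V[rec_ids[j]]
                acc = 0.0
                for i in range(N):
                    gAi = xAoff[i] - xAon[i]
                    gGi = xGoff[i] - xGon[i]
                    gNi = xNoff[i] - xNon[i]
                    sNi = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * V[i]))
                    acc += gAi * (V[i] - ErevA) + gGi * (V[i] - ErevG) \
                        + gNi * sNi * (V[i] - ErevN)
                lfp[next_sample] = acc
                next_sample += 1
            continue
        h2 = 0.5 * h

        fAon = np.exp(-h2 / tau_onA); fAoff = np.exp(-h2 / tau_offA)
        fGon = np.exp(-h2 / tau_onG); fGoff = np.exp(-h2 / tau_offG)
        fNon = np.exp(-h2 / tau_onN); fNoff = np.exp(-h2 / tau_offN)

        # conductance states at the midpoint
        for i in range(N):
            mAon[i] = xAon[i] * fAon; mAoff[i] = xAoff[i] * fAoff
            mGon[i] = xGon[i] * fGon; mGoff[i] = xGoff[i] * fGoff
            mNon[i] = xNon[i] * fNon; mNoff[i] = xNoff[i] * fNoff

        # fast mode: fold deliveries arriving inside (t, t+h] in analytically
        nev = 0
        if not event_split:
            tmid = t + h2
            while hn > 0 and ht[0] <= t_next + _EPS:
                td, idx, amp, hn = _heap_pop(ht, hi, ha, hn)
                if idx >= 0:
                    p = syn_post[idx]
                    dgA = amp * syn_gA[idx] * normA
                    dgG = amp * syn_gG[idx] * normG
                    dgN = amp * syn_gN[idx] * normN
                else:
                    k = -idx - 1
                    p = ext_post[k]
                    dgA = ext_gA[k] * normA
                    dgG = ext_gG[k] * normG
                    dgN = ext_gN[k] * normN
                if td <= tmid:
                    dm = tmid - td
                    mAon[p] += dgA * np.exp(-dm / tau_onA)
                    mAoff[p] += dgA * np.exp(-dm / tau_offA)
                    mGon[p] += dgG * np.exp(-dm / tau_onG)
                    mGoff[p] += dgG * np.exp(-dm / tau_offG)
                    mNon[p] += dgN * np.exp(-dm / tau_onN)
                    mNoff[p] += dgN * np.exp(-dm / tau_offN)
                else:
                    if nev >= evb_cap:
                        evb_cap *= 2
                        a1 = np.empty(evb_cap); a1[:nev] = evb_td[:nev]; evb_td = a1
                        a2 = np.empty(evb_cap, dtype=np.int64); a2[:nev] = evb_post[:nev]; evb_post = a2
                        a3 = np.empty(evb_cap); a3[:nev] = evb_gA[:nev]; evb_gA = a3
                        a4 = np.empty(evb_cap); a4[:nev] = evb_gG[:nev]; evb_gG = a4
                        a5 = np.empty(evb_cap); a5[:nev] = evb_gN[:nev]; evb_gN = a5
                    evb_td[nev] = td
                    evb_post[nev] = p
                    evb_gA[nev] = dgA
                    evb_gG[nev] = dgG
                    evb_gN[nev] = dgN
                    nev += 1

        n_emit = 0
        diverged = False
        for i in range(N):
            Vi = V[i]; wi = w[i]
            gA0 = xAoff[i] - xAon[i]
            gG0 = xGoff[i] - xGon[i]
            gN0 = xNoff[i] - xNon[i]
            # k1
            sN = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * Vi))
            Isyn = gA0 * (Vi - ErevA) + gG0 * (Vi - ErevG) + gN0 * sN * (Vi - ErevN)
            I1 = Ibg[i] - Isyn
            eT = np.exp((Vi - Vth[i]) / DT[i])
            wv = -gL[i] * (Vi - EL[i]) + gL[i] * DT[i] * eT + I1
            above0 = (wi - wv) > rband[i] * wv
            outside0 = above0 or (wv - wi) > rband[i] * wv
            dV1 = (wv - wi) / C[i]
            if outside0 or Vi >= Vth[i]:
                dw1 = 0.0
            else:
                dw1 = (1.0 - rband[i]) * (gL[i] * (eT - 1.0)) * dV1
            Vm = Vi + h2 * dV1
            wm = wi + h2 * dw1
            # k2 at the midpoint
            gAm = mAoff[i] - mAon[i]
            gGm = mGoff[i] - mGon[i]
            gNm = mNoff[i] - mNon[i]
            sNm = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * Vm))
            Isyn_m = gAm * (Vm - ErevA) + gGm * (Vm - ErevG) + gNm * sNm * (Vm - ErevN)
            I2 = Ibg[i] - Isyn_m
            eTm = np.exp((Vm - Vth[i]) / DT[i])
            wvm = -gL[i] * (Vm - EL[i]) + gL[i] * DT[i] * eTm + I2
            outsidem = abs(wm - wvm) > rband[i] * wvm
            dV2 = (wvm - wm) / C[i]
            if outsidem or Vm >= Vth[i]:
                dw2 = 0.0
            else:
                dw2 = (1.0 - rband[i]) * (gL[i] * (eTm - 1.0)) * dV2
            Vn = Vi + h * dV2
            wn = wi + h * dw2
            isyn_int[i] -= Isyn_m * h  # signed current into the cell

            # projection on crossing the upper band edge from above
            if above0:
                gAe = mAoff[i] * fAoff - mAon[i] * fAon
                gGe = mGoff[i] * fGoff - mGon[i] * fGon
                gNe = mNoff[i] * fNoff - mNon[i] * fNon
                sNe = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * Vn))
                Ie = Ibg[i] - (gAe * (Vn - ErevA) + gGe * (Vn - ErevG)
                               + gNe * sNe * (Vn - ErevN))
                wve = -gL[i] * (Vn - EL[i]) \
                    + gL[i] * DT[i] * np.exp((Vn - Vth[i]) / DT[i]) + Ie
                if (wn - wve) <= rband[i] * wve:
                    wn = (1.0 - rband[i]) * wve

            # hyperpolarization floor: extreme adaptation transients would
            # otherwise drive a deep sawtooth far outside the model's
            # validity; project the state onto the band boundary instead
            if Vn < -200.0:
                Vn = -200.0
                gAe = mAoff[i] * fAoff - mAon[i] * fAon
                gGe = mGoff[i] * fGoff - mGon[i] * fGon
                gNe = mNoff[i] * fNoff - mNon[i] * fNon
                sNe = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * Vn))
                Ie = Ibg[i] - (gAe * (Vn - ErevA) + gGe * (Vn - ErevG)
                               + gNe * sNe * (Vn - ErevN))
                wve = -gL[i] * (Vn - EL[i]) \
                    + gL[i] * DT[i] * np.exp((Vn - Vth[i]) / DT[i]) + Ie
                cap_w = (1.0 + rband[i]) * wve
                if wn > cap_w:
                    wn = cap_w

            if Vn > Vup[i]:
                frac = (Vup[i] - Vi) / (Vn - Vi)
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
                emit[n_emit] = i
                emit_t[n_emit] = t + frac * h
                n_emit += 1
                Vn = Vr[i]
                wn = wn + b_inc[i]
                # advance the post-reset remainder of the step (2nd order,
                # conductances held at their end-of-step values)
                h_rem = (1.0 - frac) * h
                if h_rem > 1e-9:
                    gAe = mAoff[i] * fAoff - mAon[i] * fAon
                    gGe = mGoff[i] * fGoff - mGon[i] * fGon
                    gNe = mNoff[i] * fNoff - mNon[i] * fNon
                    for _sub in range(2):
                        hh = h_rem * 0.5
                        # midpoint step on (V, w) at frozen conductances
                        sN1 = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * Vn))
                        I1r = Ibg[i] - (gAe * (Vn - ErevA) + gGe * (Vn - ErevG)
                                        + gNe * sN1 * (Vn - ErevN))
                        eT1 = np.exp((Vn - Vth[i]) / DT[i])
                        wv1 = -gL[i] * (Vn - EL[i]) + gL[i] * DT[i] * eT1 + I1r
                        dV1r = (wv1 - wn) / C[i]
                        if abs(wn - wv1) > rband[i] * wv1 or Vn >= Vth[i]:
                            dw1r = 0.0
                        else:
                            dw1r = (1.0 - rband[i]) * gL[i] * (eT1 - 1.0) * dV1r
                        Vmr = Vn + 0.5 * hh * dV1r
                        wmr = wn + 0.5 * hh * dw1r
                        sN2 = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * Vmr))
                        I2r = Ibg[i] - (gAe * (Vmr - ErevA) + gGe * (Vmr - ErevG)
                                        + gNe * sN2 * (Vmr - ErevN))
                        eT2 = np.exp((Vmr - Vth[i]) / DT[i])
                        wv2 = -gL[i] * (Vmr - EL[i]) + gL[i] * DT[i] * eT2 + I2r
                        dV2r = (wv2 - wmr) / C[i]
                        if abs(wmr - wv2) > rband[i] * wv2 or Vmr >= Vth[i]:
                            dw2r = 0.0
                        else:
                            dw2r = (1.0 - rband[i]) * gL[i] * (eT2 - 1.0) * dV2r
                        Vn = Vn + hh * dV2r
                        wn = wn + hh * dw2r
                    # under extreme drive the remainder can re-cross the
                    # threshold within the same step; park at V_up so the
                    # next step registers the crossing (no double count)
                    if Vn > Vup[i]:
                        Vn = Vup[i]
            if not (-1000.0 < Vn < 1000.0) or not np.isfinite(wn):
                diverged = True
            V[i] = Vn
            w[i] = wn

        if diverged:
            return (STATUS_DIVERGED, t, sp_nrn[:sp_n], sp_t[:sp_n],
                    Vrec, lfp, isyn_int, V, w)

        # conductance states to the step end
        for i in range(N):
            xAon[i] = mAon[i] * fAon; xAoff[i] = mAoff[i] * fAoff
            xGon[i] = mGon[i] * fGon; xGoff[i] = mGoff[i] * fGoff
            xNon[i] = mNon[i] * fNon; xNoff[i] = mNoff[i] * fNoff
        for e in range(nev):
            p = evb_post[e]
            de = t_next - evb_td[e]
            xAon[p] += evb_gA[e] * np.exp(-de / tau_onA)
            xAoff[p] += evb_gA[e] * np.exp(-de / tau_offA)
            xGon[p] += evb_gG[e] * np.exp(-de / tau_onG)
            xGoff[p] += evb_gG[e] * np.exp(-de / tau_offG)
            xNon[p] += evb_gN[e] * np.exp(-de / tau_onN)
            xNoff[p] += evb_gN[e] * np.exp(-de / tau_offN)

        # spike bookkeeping: record, update presynaptic dynamics, schedule
        for e in range(n_emit):
            i = emit[e]
            tc = emit_t[e]
            if sp_n >= sp_cap:
                sp_cap *= 2
                a1 = np.empty(sp_cap, dtype=np.int64); a1[:sp_n] = sp_nrn[:sp_n]; sp_nrn = a1
                a2 = np.empty(sp_cap); a2[:sp_n] = sp_t[:sp_n]; sp_t = a2
            sp_nrn[sp_n] = i
            sp_t[sp_n] = tc
            sp_n += 1
            for jj in range(out_ptr[i], out_ptr[i + 1]):
                s = out_idx[jj]
                if stp_tl[s] < -1.0e29:
                    u = syn_U[s]
                    R = 1.0
                else:
                    delta = tc - stp_tl[s]
                    if delta < 1e-6:
                        delta = 1e-6
                    u = syn_U[s] + stp_u[s] * (1.0 - syn_U[s]) * np.exp(-delta / syn_taufac[s])
                    R = 1.0 + (stp_R[s] - stp_u[s] * stp_R[s] - 1.0) * np.exp(-delta / syn_taurec[s])
                stp_u[s] = u
                stp_R[s] = R
                stp_tl[s] = tc
                if np.random.random() >= syn_pfail[s]:
                    if hn >= cap:
                        cap *= 2
                        ht2 = np.empty(cap); ht2[:hn] = ht[:hn]; ht = ht2
                        hi2 = np.empty(cap, dtype=np.int64); hi2[:hn] = hi[:hn]; hi = hi2
                        ha2 = np.empty(cap); ha2[:hn] = ha[:hn]; ha = ha2
                    hn = _heap_push(ht, hi, ha, hn, tc + syn_delay[s], s, u * R)

        t = t_next
        if next_sample < n_samples and t >= next_sample * sample_dt - _EPS:
            if record_v:
                for j in range(n_rec):
                    Vrec[j, next_sample] = V[rec_ids[j]]
            acc = 0.0
            for i in range(N):
                gAi = xAoff[i] - xAon[i]
                gGi = xGoff[i] - xGon[i]
                gNi = xNoff[i] - xNon[i]
                sNi = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * V[i]))
                acc += gAi * (V[i] - ErevA) + gGi * (V[i] - ErevG) \
                    + gNi * sNi * (V[i] - ErevN)
            lfp[next_sample] = acc
            next_sample += 1

    return (STATUS_OK, t, sp_nrn[:sp_n], sp_t[:sp_n],
            Vrec, lfp, isyn_int, V, w)
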