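"""Event-driven network simulation core.

The engine keeps pending synaptic deliveries in a calendar queue — a ring
of fixed-width time buckets — and processes them in time order.  Because
every synaptic delay exceeds the bucket width, a bucket can be sorted and
drained without ever receiving new events, which makes the queue O(1) per
event where a binary heap would pay a logarithmic sift.  Each delivery
lazily advances the postsynaptic neuron along its closed-form exponential
decays, applies the stepwise driving-force increment, and checks the spike
conditions (threshold crossing, not refractory, below the depolarization
blockade).  A spike tags eligible incoming plastic synapses (causal pre
spike within the STDP window), applies the post-spike bookkeeping and
schedules deliveries on all outgoing synapses.

The hot loop is compiled with numba; all state lives in flat numpy arrays so
the kernel is resumable (it returns when buffers need to grow and continues
where it stopped).  Semantics match the scalar reference in
:mod:`snnpong.neurons` exactly — a dedicated test drives both on the same
event sequence.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np
from numba import njit

from .synapses import SYNAPSE_KINDS, SynapseParams

__all__ = ["EventEngine"]

_E_SYN = np.array([SynapseParams.of(k).e_syn for k in SYNAPSE_KINDS])
_TAU_SYN = np.array([SynapseParams.of(k).tau_syn for k in SYNAPSE_KINDS])

_OK, _GROW_BUCKETS, _GROW_SPIKES = 0, 1, 2

#: Bucket width in ms; must stay below the smallest synaptic delay so that
#: draining a bucket can never schedule into that same bucket.
_BUCKET_W = 0.2
#: Ring length; the horizon _BUCKET_W * _N_BUCKETS must exceed the longest
#: scheduling lookahead (one action interval plus the largest delay).
_N_BUCKETS = 1024


@njit(cache=True)
def _run(b_t, b_s, b_n, bucket_cap, cur_k, t_end,
         scr_t, scr_s, scr_state,
         s_post, s_kind, s_w, s_delay, s_plastic, s_last_pre, s_tag,
         vsyn, vahp, dthr, last, refr,
         p_vrest, p_vthresh, p_vblock, p_tauar, p_wrr, p_taurr,
         p_dvahp, p_tauahp,
         out_ptr, out_idx, inp_ptr, inp_idx,
         e_syn, tau_syn, stdp_window, max_fanout,
         sp_t, sp_i, sp_n):
    """Drain the calendar queue up to ``t_end``.

    ``scr_*`` is the persistent scratch holding the sorted contents of the
    bucket currently being drained (``scr_state = [pos, cnt]``), so the
    kernel can return for buffer growth and resume exactly where it was.
    """
    n_buckets = len(b_n)
    k_end = np.int64(t_end / _BUCKET_W)
    headroom = np.int64(np.max(b_n))
    while True:
        pos, cnt = scr_state[0], scr_state[1]
        if pos >= cnt:
            # load the next non-empty bucket at or before k_end
            k = cur_k[0]
            while k <= k_end and b_n[k % n_buckets] == 0:
                k += 1
            if k > k_end:
                # stop at the boundary bucket: it may still receive events
                cur_k[0] = k_end
                return _OK
            cur_k[0] = k
            bi = k % n_buckets
            m = b_n[bi]
            order = np.argsort(b_t[bi, :m])
            for i in range(m):
                scr_t[i] = b_t[bi, order[i]]
                scr_s[i] = b_s[bi, order[i]]
            b_n[bi] = 0
            scr_state[0], scr_state[1] = 0, m
            pos, cnt = 0, m
            continue
        t = scr_t[pos]
        if t > t_end:
            return _OK  # remainder of this bucket belongs to a later call
        if headroom + max_fanout > bucket_cap:
            return _GROW_BUCKETS
        if sp_n[0] + 1 > len(sp_t):
            return _GROW_SPIKES
        scr_state[0] = pos + 1
        s = scr_s[pos]
        j = s_post[s]
        dt = t - last[j]
        if dt > 0.0:
            for k4 in range(4):
                v = vsyn[j, k4]
                if v != 0.0:
                    vsyn[j, k4] = v * math.exp(-dt / tau_syn[k4])
            if vahp[j] != 0.0:
                vahp[j] *= math.exp(-dt / p_tauahp[j])
            if dthr[j] != 0.0:
                dthr[j] *= math.exp(-dt / p_taurr[j])
            last[j] = t
        vdev = vsyn[j, 0] + vsyn[j, 1] - vsyn[j, 2] - vsyn[j, 3] - vahp[j]
        k4 = s_kind[s]
        vsyn[j, k4] += s_w[s] * (1.0 - vdev / e_syn[k4])
        if s_plastic[s]:
            s_last_pre[s] = t - s_delay[s]  # presynaptic spike time
        vm = (p_vrest[j] + vsyn[j, 0] + vsyn[j, 1]
              - vsyn[j, 2] - vsyn[j, 3] - vahp[j])
        if vm >= p_vthresh[j] + dthr[j] and vm <= p_vblock[j] and t >= refr[j]:
            sp_t[sp_n[0]] = t
            sp_i[sp_n[0]] = j
            sp_n[0] += 1
            for q in range(inp_ptr[j], inp_ptr[j + 1]):
                s2 = inp_idx[q]
                dpre = t - s_last_pre[s2]
                if 0.0 < dpre <= stdp_window:
                    s_tag[s2] = t
            vahp[j] += p_dvahp[j]
            refr[j] = t + p_tauar[j]
            dthr[j] = p_wrr[j] * (p_vblock[j] - p_vthresh[j])
            for q in range(out_ptr[j], out_ptr[j + 1]):
                s3 = out_idx[q]
                ta = t + s_delay[s3]
                bi = np.int64(ta / _BUCKET_W) % n_buckets
                b_t[bi, b_n[bi]] = ta
                b_s[bi, b_n[bi]] = s3
                b_n[bi] += 1
                if b_n[bi] > headroom:
                    headroom = b_n[bi]


class EventEngine:
    """Runs one :class:`~snnpong.network.Network` forward in time.

    The engine owns the dynamic state (synaptic voltages, AHP, thresholds,
    refractory clocks, pending deliveries, eligibility tags); the network
    object owns the static structure and the weights, which the engine reads
    live so that plasticity updates between intervals take effect
    immediately.
    """

    def __init__(self, net, stdp_window: float = 10.0):
        self.net = net
        self.stdp_window = float(stdp_window)
        n, S = net.n_neurons, len(net.s_pre)
        self.vsyn = np.zeros((n, 4))
        self.vahp = np.zeros(n)
        self.dthr = np.zeros(n)
        self.last = np.zeros(n)
        self.refr = np.full(n, -1e18)
        self.last_pre = np.full(S, -1e18)
        self.tag_time = np.full(S, -1e18)
        self.now = 0.0
        self._bucket_cap = 256
        self._b_t = np.empty((_N_BUCKETS, self._bucket_cap))
        self._b_s = np.empty((_N_BUCKETS, self._bucket_cap), dtype=np.int64)
        self._b_n = np.zeros(_N_BUCKETS, dtype=np.int64)
        self._cur_k = np.zeros(1, dtype=np.int64)
        self._scr_t = np.empty(self._bucket_cap)
        self._scr_s = np.empty(self._bucket_cap, dtype=np.int64)
        self._scr_state = np.zeros(2, dtype=np.int64)
        self._pending_t = np.empty(0)
        self._pending_s = np.empty(0, dtype=np.int64)
        self._spike_cap = 8192
        if len(net.out_ptr) != n + 1:
            raise ValueError("network not finalized")
        deg = np.diff(net.out_ptr)
        self._max_fanout = int(deg.max()) if len(deg) else 0
        if net.s_delay.size and net.s_delay.min() <= _BUCKET_W:
            raise ValueError("synaptic delays must exceed the bucket width")

    # -- state management ------------------------------------------------------

    def reset_state(self, t0: float = 0.0) -> None:
        """Reset all dynamic state (weights are untouched)."""
        self.vsyn[:] = 0.0
        self.vahp[:] = 0.0
        self.dthr[:] = 0.0
        self.last[:] = t0
        self.refr[:] = -1e18
        self.last_pre[:] = -1e18
        self.tag_time[:] = -1e18
        self._b_n[:] = 0
        self._cur_k[0] = int(t0 / _BUCKET_W)
        self._scr_state[:] = 0
        self._pending_t = np.empty(0)
        self._pending_s = np.empty(0, dtype=np.int64)
        self.now = t0

    def schedule_external(self, syn_ids: np.ndarray, spike_times: np.ndarray) -> None:
        """Queue deliveries for external drive synapses.

        ``spike_times`` are source spike times; each delivery arrives after
        the synapse's fixed conduction delay.  Arrivals beyond the calendar
        horizon are parked in an overflow list and enter the calendar as the
        simulation catches up.
        """
        arrivals = np.asarray(spike_times, dtype=float) + \
            self.net.s_delay[syn_ids]
        if arrivals.size == 0:
            return
        if arrivals.min() < self.now:
            raise ValueError("cannot schedule an event in the past")
        self._pending_t = np.concatenate([self._pending_t, arrivals])
        self._pending_s = np.concatenate([self._pending_s,
                                          np.asarray(syn_ids, dtype=np.int64)])
        self._admit_pending()

    def _admit_pending(self) -> None:
        """Move overflow events inside the horizon into the calendar."""
        if not len(self._pending_t):
            return
        base = self._cur_k[0] * _BUCKET_W
        limit = base + (_N_BUCKETS - 2) * _BUCKET_W
        take = self._pending_t < limit
        if not take.any():
            return
        arrivals = self._pending_t[take]
        syn_ids = self._pending_s[take]
        self._pending_t = self._pending_t[~take]
        self._pending_s = self._pending_s[~take]
        ks = (arrivals / _BUCKET_W).astype(np.int64) % _N_BUCKETS
        need = (self._b_n + np.bincount(ks, minlength=_N_BUCKETS)).max()
        while need > self._bucket_cap:
            self._grow_buckets()
        for ta, s, bi in zip(arrivals, syn_ids, ks):
            m = self._b_n[bi]
            self._b_t[bi, m] = ta
            self._b_s[bi, m] = s
            self._b_n[bi] = m + 1

    def _grow_buckets(self) -> None:
        cap = 2 * self._bucket_cap
        b_t = np.empty((_N_BUCKETS, cap))
        b_s = np.empty((_N_BUCKETS, cap), dtype=np.int64)
        b_t[:, : self._bucket_cap] = self._b_t
        b_s[:, : self._bucket_cap] = self._b_s
        self._b_t, self._b_s = b_t, b_s
        scr_t = np.empty(cap)
        scr_s = np.empty(cap, dtype=np.int64)
        m = self._scr_state[1]
        scr_t[:m] = self._scr_t[:m]
        scr_s[:m] = self._scr_s[:m]
        self._scr_t, self._scr_s = scr_t, scr_s
        self._bucket_cap = cap

    # -- simulation ------------------------------------------------------------

    def run_until(self, t_end: float) -> Tuple[np.ndarray, np.ndarray]:
        """Process all deliveries up to ``t_end``; returns (times, neuron ids)."""
        if t_end < self.now:
            raise ValueError("time must not run backward")
        net = self.net
        p = net.params
        spikes_t = [np.empty(0)]
        spikes_i = [np.empty(0, dtype=np.int64)]
        sp_t = np.empty(self._spike_cap)
        sp_i = np.empty(self._spike_cap, dtype=np.int64)
        while True:
            # advance at most one calendar horizon at a time so that parked
            # overflow events can enter the ring as time catches up
            self._admit_pending()
            base = self._cur_k[0] * _BUCKET_W
            chunk_end = min(t_end, base + (_N_BUCKETS - 4) * _BUCKET_W)
            sp_n = np.zeros(1, dtype=np.int64)
            status = _run(
                self._b_t, self._b_s, self._b_n, self._bucket_cap,
                self._cur_k, chunk_end,
                self._scr_t, self._scr_s, self._scr_state,
                net.s_post, net.s_kind, net.s_w, net.s_delay, net.s_plastic,
                self.last_pre, self.tag_time,
                self.vsyn, self.vahp, self.dthr, self.last, self.refr,
                p["v_rest"], p["v_thresh"], p["v_block"], p["tau_ar"],
                p["w_rr"], p["tau_rr"], p["dv_ahp"], p["tau_ahp"],
                net.out_ptr, net.out_idx, net.inp_ptr, net.inp_idx,
                _E_SYN, _TAU_SYN, self.stdp_window, self._max_fanout,
                sp_t, sp_i, sp_n)
            spikes_t.append(sp_t[: sp_n[0]].copy())
            spikes_i.append(sp_i[: sp_n[0]].copy())
            if status == _GROW_BUCKETS:
                self._grow_buckets()
            elif status == _GROW_SPIKES:
                self._spike_cap *= 2
                sp_t = np.empty(self._spike_cap)
                sp_i = np.empty(self._spike_cap, dtype=np.int64)
            elif chunk_end >= t_end:
                break
            self.now = chunk_end
        self.now = t_end
        return np.concatenate(spikes_t), np.concatenate(spikes_i)

    # -- plasticity hooks ------------------------------------------------------

    def eligibility(self, t: float, tau: float,
                    idx: np.ndarray | None = None) -> np.ndarray:
        """Eligibility trace values at time ``t`` (optionally only at ``idx``)."""
        tags = self.tag_time if idx is None else self.tag_time[idx]
        age = t - tags
        out = np.zeros(len(tags))
        live = age < 50.0 * tau  # exp underflow guard
        out[live] = np.exp(-age[live] / tau)
        return out
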