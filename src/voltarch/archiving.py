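"""Postsynaptic archiving: storage, read-out and compression of plasticity signals.

Synapses in an event-driven scheme are only touched when a spike crosses
them, so the postsynaptic neuron must archive the signal a synapse will
eventually need: a thresholded voltage product for Clopath LTP (sparse in
time, because the thresholds zero it out away from postsynaptic spikes) or
the dendritic prediction error for the Urbanczik-Senn rule (dense, one value
per grid step).  Each stored entry carries an access counter; once every one
of the ``K`` incoming plastic connections has read an entry it can never be
requested again and is garbage collected.

The compressed variant stores, per distinct last-presynaptic-spike time, a
partially accumulated integral of the postsynaptic signal weighted with the
exponential presynaptic-trace kernel.  Because that kernel enters only
through an exponential prefactor, a chunk integrated once can advance the
accumulator of *every* incoming connection (see :func:`compress_and_advance`).

All times are integer grid steps; milliseconds appear only at I/O
boundaries.  History intervals are half-open ``(t_from, t_to]``.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field


class HistoryUnderrunError(RuntimeError):
    """A synapse requested a history segment that was already pruned.

    This always signals a bookkeeping bug (garbage collection ran ahead of
    a reader), never a recoverable condition.
    """


class HistoryOrderError(ValueError):
    """Out-of-order write into a history."""


@dataclass
class HistoryEntry:
    """One archived value: grid step, signal value, and read count."""

    t_step: int
    value: float
    access_counter: int = 0


class _History:
    """Ordered run of :class:`HistoryEntry`, consumed oldest-first.

    ``pruned_through`` is the newest step that is guaranteed unavailable;
    reads reaching at or below it raise :class:`HistoryUnderrunError`.
    """

    continuous = False

    def __init__(self, pruned_through: int = -(10**9)):
        self.entries: deque[HistoryEntry] = deque()
        self.pruned_through = pruned_through
        self._last_step: int | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def write(self, t_step: int, value: float, counters=None) -> None:
        if self._last_step is not None:
            if self.continuous and t_step != self._last_step + 1:
                raise HistoryOrderError(
                    f"continuous history expects step {self._last_step + 1}, "
                    f"got {t_step}"
                )
            if not self.continuous and t_step <= self._last_step:
                raise HistoryOrderError(
                    f"non-increasing step {t_step} after {self._last_step}"
                )
        self._last_step = t_step
        if not self.continuous and value == 0.0:
            return  # sparse histories store non-zero values only
        self.entries.append(HistoryEntry(t_step, value))
        if counters is not None:
            counters.H += 1

    def get_segment(self, t_from: int, t_to: int) -> list[HistoryEntry]:
        """Entries with ``t_from < t_step <= t_to``; bumps access counters."""
        if t_from > t_to:
            raise ValueError(f"empty-negative interval ({t_from}, {t_to}]")
        if t_from < self.pruned_through:
            raise HistoryUnderrunError(
                f"segment ({t_from}, {t_to}] reaches below pruned step "
                f"{self.pruned_through}"
            )
        out = []
        for e in self.entries:
            if e.t_step > t_to:
                break
            if e.t_step > t_from:
                e.access_counter += 1
                out.append(e)
        return out

    def prune(self, k: int) -> int:
        """Drop the maximal front run of entries read by all ``k`` readers."""
        n = 0
        while self.entries and self.entries[0].access_counter >= k:
            dropped = self.entries.popleft()
            self.pruned_through = max(self.pruned_through, dropped.t_step)
            n += 1
        return n

    def prune_through(self, t_step: int) -> int:
        """Unconditionally drop entries up to and including ``t_step``.

        Used by the compressed scheme, where the integration frontier, not
        access counting, decides what is still needed.
        """
        n = 0
        while self.entries and self.entries[0].t_step <= t_step:
            self.entries.popleft()
            n += 1
        self.pruned_through = max(self.pruned_through, t_step)
        return n


class SparseHistory(_History):
    """Time-stamped non-zero values (Clopath LTP signal)."""

    continuous = False


class ContinuousHistory(_History):
    """One value per grid step (Urbanczik-Senn prediction error)."""

    continuous = True


# -- spec-surface free functions ------------------------------------------

def write_history(hist: _History, t_step: int, value: float, counters=None) -> None:
    hist.write(t_step, value, counters)


def get_history_segment(hist: _History, t_from: int, t_to: int) -> list[HistoryEntry]:
    return hist.get_segment(t_from, t_to)


def prune_history(hist: _History, k: int) -> int:
    return hist.prune(k)


# -- compressed history ----------------------------------------------------

@dataclass
class _CompressedEntry:
    values: list[float]      # accumulators, one per integral kind (I1[, I2])
    refcount: int = 1


class CompressedHistory:
    """Map last-spike step -> partially accumulated postsynaptic integral.

    Key ``t_ref`` holds, after advancing to the shared frontier ``t_proc``,

        acc1 = sum_{t_ref < b <= t_proc} exp(-(b - t_ref) h / tau_s) V*(b) h

    and, when a second (kappa) time constant is given, additionally

        acc2 = sum_{t_ref < b <= t_proc}
               exp(-(t_proc - b) h / tau_k) exp(-(b - t_ref) h / tau_s) V*(b) h

    which is the I1/I2 pair of the Urbanczik-Senn update.  Keys are shifted
    by the dendritic delay, i.e. ``t_ref = t_LS - d``.
    """

    def __init__(self, tau_s_ms: float, h_ms: float, tau_k_ms: float | None = None,
                 t_proc: int = 0):
        self.tau_s_ms = tau_s_ms
        self.tau_k_ms = tau_k_ms
        self.h_ms = h_ms
        self.t_proc = t_proc
        self.entries: dict[int, _CompressedEntry] = {}

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_values(self) -> int:
        return 2 if self.tau_k_ms is not None else 1

    def register_key(self, t_ref: int) -> None:
        """Declare a connection whose last (virtual) spike is ``t_ref``."""
        if t_ref > self.t_proc:
            raise ValueError("compressed key ahead of processed frontier")
        e = self.entries.get(t_ref)
        if e is None:
            self.entries[t_ref] = _CompressedEntry([0.0] * self.n_values)
        else:
            e.refcount += 1


def compress_and_advance(comp: CompressedHistory, segment, t_new: int,
                         counters=None) -> None:
    """Integrate ``segment`` once and advance every stored accumulator.

    ``segment`` must cover ``(comp.t_proc, t_new]`` (entries outside raise).
    Uses the decomposition  dW(t_ref, t_new) = dW(t_ref, t_proc)
    + exp(-(t_proc - t_ref) h / tau_s) * dW(t_proc, t_new),  so the raw
    segment is integrated exactly once regardless of the number of incoming
    connections.  Every key strictly older than ``t_new`` is touched (one
    history-entry manipulation each, even when the chunk is empty); keys
    equal to ``t_new`` were created in the same delivery batch and are
    vacuous, hence skipped.
    """
    h = comp.h_ms
    t0 = comp.t_proc
    chunk1 = 0.0
    chunk2 = 0.0
    for e in segment:
        if not (t0 < e.t_step <= t_new):
            raise ValueError(
                f"segment entry at step {e.t_step} outside ({t0}, {t_new}]"
            )
        g = math.exp(-(e.t_step - t0) * h / comp.tau_s_ms) * e.value * h
        chunk1 += g
        if comp.tau_k_ms is not None:
            chunk2 += math.exp(-(t_new - e.t_step) * h / comp.tau_k_ms) * e.value \
                * math.exp(-(e.t_step - t0) * h / comp.tau_s_ms) * h
    if counters is not None:
        counters.C += len(segment)
    decay_k = (math.exp(-(t_new - t0) * h / comp.tau_k_ms)
               if comp.tau_k_ms is not None else None)
    for t_ref, entry in comp.entries.items():
        if t_ref == t_new:
            continue
        pref = math.exp(-(t0 - t_ref) * h / comp.tau_s_ms)
        entry.values[0] += pref * chunk1
        if comp.tau_k_ms is not None:
            entry.values[1] = entry.values[1] * decay_k + pref * chunk2
        if counters is not None:
            counters.H += 1
    comp.t_proc = t_new


def read_and_reset_compressed(comp: CompressedHistory, t_ref_old: int,
                              t_new: int) -> list[float]:
    """Read the accumulator for ``t_ref_old`` and re-key the synapse to ``t_new``.

    The old key is removed only when no other synapse shares it (reference
    count); the new key starts (or continues, for synchronous arrivals) at
    zero accumulated integral.
    """
    if comp.t_proc != t_new:
        raise RuntimeError(
            f"read at step {t_new} but frontier is {comp.t_proc}"
        )
    entry = comp.entries.get(t_ref_old)
    if entry is None:
        raise KeyError(
            f"compressed history has no entry for last-spike step {t_ref_old}"
        )
    values = list(entry.values)
    entry.refcount -= 1
    if entry.refcount == 0:
        del comp.entries[t_ref_old]
    comp.register_key(t_new)
    return values


class DelayRingBuffer:
    """Cyclic buffer of the delayed low-pass potential (Clopath LTD read)."""

    def __init__(self, capacity: int, fill: float = 0.0):
        if capacity < 1:
            raise ValueError("ring buffer capacity must be >= 1")
        self.capacity = capacity
        self._buf = [fill] * capacity
        self._t_last = -1

    def write(self, t_step: int, value: float) -> None:
        self._buf[t_step % self.capacity] = value
        self._t_last = t_step

    def read(self, t_step: int, d_steps: int) -> float:
        if d_steps > self.capacity - 1:
            raise ValueError(
                f"lag {d_steps} exceeds ring buffer capacity {self.capacity}"
            )
        if d_steps < 0:
            raise ValueError("negative lag")
        return self._buf[(t_step - d_steps) % self.capacity]


def delayed_voltage(ring: DelayRingBuffer, t_step: int, d_steps: int) -> float:
    return ring.read(t_step, d_steps)


class SpikeArchive:
    """Postsynaptic spike steps with post-trace values (STDP).

    The trace is the exponentially filtered postsynaptic spike train with
    time constant ``tau_minus``; the stored value is the post-increment
    trace at the spike.  Entries carry access counters and are pruned with
    the same in-degree criterion as the voltage histories.
    """

    def __init__(self, tau_minus_ms: float, h_ms: float):
        self.tau_minus_ms = tau_minus_ms
        self.h_ms = h_ms
        self.hist = SparseHistory()
        self._trace = 0.0
        self._t_last: int | None = None

    def __len__(self) -> int:
        return len(self.hist)

    def set_spiketime(self, t_step: int, counters=None) -> None:
        if self._t_last is not None:
            dt = (t_step - self._t_last) * self.h_ms
            self._trace *= math.exp(-dt / self.tau_minus_ms)
        self._trace += 1.0 / self.tau_minus_ms
        self._t_last = t_step
        self.hist.write(t_step, self._trace, counters)

    def trace_at(self, t_step: int) -> float:
        """Post trace propagated analytically to ``t_step``."""
        if self._t_last is None or t_step < self._t_last:
            return 0.0
        dt = (t_step - self._t_last) * self.h_ms
        return self._trace * math.exp(-dt / self.tau_minus_ms)

    def get_segment(self, t_from: int, t_to: int):
        return self.hist.get_segment(t_from, t_to)

    def prune(self, k: int) -> int:
        return self.hist.prune(k)


def dump_history_csv(hist, path, h_ms: float) -> None:
    """Debug dump: columns t_ms, value, access_counter."""
    with open(path, "w") as fh:
        fh.write("t_ms,value,access_counter\n")
        entries = hist.hist.entries if isinstance(hist, SpikeArchive) else hist.entries
        for e in entries:
            fh.write(f"{e.t_step * h_ms:.1f},{e.value!r},{e.access_counter}\n")
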