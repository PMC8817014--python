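"""Independent brute-force oracles, written directly from the update rules
with plain Python loops and dicts.  Deliberately shares no code with the
package so it can serve as a cross-check on small panels."""

from __future__ import annotations


def brute_force_rita(assignments, deltas, lam_l=0.05, lam_u=0.95):
    """Full tau_A trajectory for a small panel.

    ``assignments``: list over periods of lists of "A"/"B".
    ``deltas``: list over periods of lists of responses (assumed tie-free).
    Returns a list over periods of the per-individual clamped tau_A.
    """
    n = len(deltas[0])
    counts = {("A", i): 0 for i in range(n)} | {("B", i): 0 for i in range(n)}
    sums = dict(counts)
    imr = {("A", i): n / 2 for i in range(n)} | {("B", i): n / 2 for i in range(n)}
    history = []
    for arms_t, d_t in zip(assignments, deltas):
        order = sorted(range(n), key=lambda i: d_t[i])
        rank = {i: k + 1 for k, i in enumerate(order)}
        taus = []
        for i in range(n):
            arm = arms_t[i]
            other = "B" if arm == "A" else "A"
            counts[arm, i] += 1
            sums[arm, i] += rank[i]
            imr[arm, i] = sums[arm, i] / counts[arm, i]
            t_assigned = (rank[i] / n) * (
                (rank[i] / imr[other, i]) ** (counts[arm, i] - 1)
            )
            tau_a = t_assigned if arm == "A" else 1.0 - t_assigned
            tau_a = min(max(tau_a, lam_l), lam_u)
            taus.append(tau_a)
        history.append(taus)
    return history


def diff_in_means(y, is_a):
    """Two-sample difference of means with the classical pooled-variance SE."""
    ya = [v for v, a in zip(y, is_a) if a]
    yb = [v for v, a in zip(y, is_a) if not a]
    ma = sum(ya) / len(ya)
    mb = sum(yb) / len(yb)
    ss = sum((v - ma) ** 2 for v in ya) + sum((v - mb) ** 2 for v in yb)
    s2 = ss / (len(y) - 2)
    se = (s2 * (1 / len(ya) + 1 / len(yb))) ** 0.5
    return ma - mb, se
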