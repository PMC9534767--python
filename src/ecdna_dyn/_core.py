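"""Numba-compiled inner loop of the individual-based Gillespie simulation.

The population is a pure birth process: every cell divides at rate 1 if it
carries no ecDNA and at rate ``s`` otherwise.  Per-cell copy numbers live in
a flat int64 array ``cells`` (only the first ``n`` entries are alive); a
parallel int8 array ``flags`` carries an arbitrary heritable marker (used
for the chromosomal scar in CRISPR-C scenarios) that both daughters inherit
unconditionally.

Cell selection uses uniform-proposal rejection sampling: propose a cell
uniformly at random and accept it with probability ``rate(k) / max_rate``.
This keeps the per-event cost O(1) regardless of how many copy-number
classes exist, and is exactly equivalent to sampling proportional to rate.
"""

import numpy as np
from numba import njit

#: status codes returned by :func:`advance`
REACHED_SIZE = 1
REACHED_TIME = 0


@njit(cache=True)
def advance(cells, flags, n, n_pos, t, s, stop_n, stop_t, seed):  # pragma: no cover
    """Advance the birth process until population size ``stop_n`` or time
    ``stop_t``, whichever comes first.

    Mutates ``cells``/``flags`` in place; returns ``(n, n_pos, t, status)``.
    ``n_pos`` tracks the number of ecDNA+ cells so the total event rate
    ``n_pos * s + (n - n_pos)`` is O(1) per event.
    """
    np.random.seed(seed)
    max_rate = s if s > 1.0 else 1.0
    while n < stop_n:
        total_rate = n_pos * s + (n - n_pos)
        dt = np.random.exponential(1.0 / total_rate)
        if t + dt > stop_t:
            return n, n_pos, stop_t, REACHED_TIME
        t += dt
        # rejection-sample the dividing cell proportional to its rate
        while True:
            i = np.random.randint(0, n)
            k = cells[i]
            r = s if k > 0 else 1.0
            if np.random.random() * max_rate < r:
                break
        k = cells[i]
        if k > 0:
            n1 = np.random.binomial(2 * k, 0.5)
            n2 = 2 * k - n1
            cells[i] = n1
            cells[n] = n2
            if n1 == 0:
                n_pos -= 1
            if n2 > 0:
                n_pos += 1
        else:
            cells[n] = 0
        flags[n] = flags[i]
        n += 1
    return n, n_pos, t, REACHED_SIZE
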