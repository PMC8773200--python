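"""Independent naive-loop reference implementations of the descriptor math.

Deliberately written with plain Python loops and dictionaries, without
sharing any code with the package, so they can serve as oracles for the
vectorised implementations.
"""

import math

AA = "ACDEFGHIKLMNPQRSTVWY"


def aac_naive(seq):
    return [seq.count(a) / len(seq) for a in AA]


def dpc_naive(seq):
    out = []
    for a in AA:
        for b in AA:
            count = sum(
                1 for i in range(len(seq) - 1)
                if seq[i] == a and seq[i + 1] == b
            )
            out.append(count / (len(seq) - 1))
    return out


def ctd_naive(seq, schemes):
    out = []
    n = len(seq)
    for scheme in schemes:
        gmap = {}
        for gi, grp in enumerate(scheme.groups):
            for aa in grp:
                gmap[aa] = gi
        labs = [gmap[c] for c in seq]
        for g in range(3):
            out.append(labs.count(g) / n)
        for a, b in ((0, 1), (0, 2), (1, 2)):
            t = sum(1 for i in range(n - 1)
                    if {labs[i], labs[i + 1]} == {a, b})
            out.append(t / (n - 1))
        for g in range(3):
            pos = [i + 1 for i, l in enumerate(labs) if l == g]
            if not pos:
                out.extend([0.0] * 5)
            else:
                ng = len(pos)
                for pct in (0, 25, 50, 75, 100):
                    k = 1 if pct == 0 else math.ceil(pct * ng / 100)
                    out.append(100.0 * pos[k - 1] / n)
    return out


def soc_naive(seq, distance, nlag):
    """distance: mapping (a, b) -> d."""
    out = []
    for d in range(1, nlag + 1):
        out.append(sum(distance[seq[i], seq[i + d]] ** 2
                       for i in range(len(seq) - d)))
    return out


def qso_naive(seq, distance, maxlag, w):
    tau = soc_naive(seq, distance, maxlag)
    freqs = [seq.count(a) / len(seq) for a in AA]
    denom = sum(freqs) + w * sum(tau)
    return [f / denom for f in freqs] + [w * t / denom for t in tau]


def autocorrelation_naive(seq, values, maxlag, kind):
    """values: mapping residue -> property value (already standardized
    if the implementation standardizes)."""
    p = [values[c] for c in seq]
    n = len(p)
    pbar = sum(p) / n
    out = []
    for lag in range(1, maxlag + 1):
        if kind == "moreau_broto":
            out.append(sum(p[i] * p[i + lag] for i in range(n - lag))
                       / (n - lag))
        elif kind == "moran":
            den = sum((x - pbar) ** 2 for x in p) / n
            if den < 1e-12:
                out.append(0.0)
            else:
                num = sum((p[i] - pbar) * (p[i + lag] - pbar)
                          for i in range(n - lag)) / (n - lag)
                out.append(num / den)
        elif kind == "geary":
            den = sum((x - pbar) ** 2 for x in p) / (n - 1)
            if den < 1e-12:
                out.append(0.0)
            else:
                num = sum((p[i] - p[i + lag]) ** 2
                          for i in range(n - lag)) / (2 * (n - lag))
                out.append(num / den)
        else:
            raise ValueError(kind)
    return out


def random_peptide(rng, length):
    return "".join(rng.choice(list(AA)) for _ in range(length))
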