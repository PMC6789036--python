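"""Independent scoring oracle: explicit enumeration of every state path.

Walks the same local multi-hit topology the engine defines (N/B/M/I/D/E/J/C
with uniform entry and free exit) but computes scores by brute-force
recursion over complete paths, taking the max (Viterbi) or log-sum (Forward)
at the end. No dynamic programming is shared with the implementation.
"""

import math

import numpy as np

from wyldomkit.phmm_engine import _null_correction, _special_costs


def enumerate_scores(model, enc, multihit):
    """(viterbi_bits, forward_bits) by exhaustive path enumeration."""
    M, L = model.M, len(enc)
    lloop, lmove, ltej, ltec = _special_costs(L, multihit)
    msc = model.scores()["msc"]
    lt = {
        k: np.log2(np.maximum(getattr(model, k), 1e-300))
        for k in ("tmm", "tmi", "tmd", "tim", "tii", "tdm", "tdd")
    }
    entry = -math.log2(M)
    scores = []

    def go(state, k, pos, acc):
        if state == "N":
            if pos < L:
                go("N", -1, pos + 1, acc + lloop)
            go("B", -1, pos, acc + lmove)
        elif state == "B":
            if pos < L:
                for kk in range(M):
                    go("M", kk, pos + 1, acc + entry + msc[kk, enc[pos]])
        elif state == "M":
            go("E", -1, pos, acc)  # free local exit from any match state
            if k < M - 1:
                if pos < L:
                    go("M", k + 1, pos + 1,
                       acc + lt["tmm"][k] + msc[k + 1, enc[pos]])
                    go("I", k, pos + 1, acc + lt["tmi"][k])
                go("D", k + 1, pos, acc + lt["tmd"][k])
        elif state == "I":
            if pos < L:
                go("M", k + 1, pos + 1,
                   acc + lt["tim"][k] + msc[k + 1, enc[pos]])
                go("I", k, pos + 1, acc + lt["tii"][k])
        elif state == "D":
            if k < M - 1:
                if pos < L:
                    go("M", k + 1, pos + 1,
                       acc + lt["tdm"][k] + msc[k + 1, enc[pos]])
                go("D", k + 1, pos, acc + lt["tdd"][k])
        elif state == "E":
            go("C", -1, pos, acc + ltec)
            if multihit:
                go("J", -1, pos, acc + ltej)
        elif state == "J":
            if pos < L:
                go("J", -1, pos + 1, acc + lloop)
            go("B", -1, pos, acc + lmove)
        elif state == "C":
            if pos < L:
                go("C", -1, pos + 1, acc + lloop)
            else:
                scores.append(acc + lmove)

    go("N", -1, 0, 0.0)
    arr = np.array(scores) - _null_correction(L)
    return float(arr.max()), float(np.logaddexp2.reduce(arr))
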