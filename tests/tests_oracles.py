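"""Independent brute-force oracles shared by the test modules."""


def brute_force_intervals(labels, stage, m):
    """All maximal admissible stage intervals by exhaustive O(n^2) search.

    An interval [a, b] is admissible when it starts and ends on the target
    stage and contains no run of more than ``m`` consecutive other-stage
    epochs; maximal means contained in no other admissible interval.
    """
    n = len(labels)
    target = [i for i in range(n) if labels[i] == stage]
    if not target:
        return []
    admissible = []
    for a in target:
        for b in target:
            if b < a:
                continue
            run = 0
            ok = True
            for i in range(a, b + 1):
                run = 0 if labels[i] == stage else run + 1
                if run > m:
                    ok = False
                    break
            if ok:
                admissible.append((a, b))
    return [iv for iv in admissible
            if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                       for o in admissible)]
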