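"""Independent reference implementations used only as test oracles."""

from __future__ import annotations


def gotoh_oracle(q: str, s: str, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Plain-Python affine-gap local alignment (full DP, no seeding).

    Returns (score, matches, mismatches, gap_columns).  Tie-breaks mirror
    the documented convention: diagonal, then gap in subject (vertical),
    then gap in query (horizontal); gap states prefer (re)opening from the
    match state at equal score.
    """
    n, m = len(q), len(s)
    NEG = float("-inf")
    first = gap_open + gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    TH = [[0] * (m + 1) for _ in range(n + 1)]
    TE = [[0] * (m + 1) for _ in range(n + 1)]
    TF = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            eh = H[i][j - 1] - first
            ee = E[i][j - 1] - gap_extend
            if eh >= ee:
                E[i][j], TE[i][j] = eh, 1
            else:
                E[i][j], TE[i][j] = ee, 0
            fh = H[i - 1][j] - first
            ff = F[i - 1][j] - gap_extend
            if fh >= ff:
                F[i][j], TF[i][j] = fh, 1
            else:
                F[i][j], TF[i][j] = ff, 0
            diag = H[i - 1][j - 1] + (match if qi == s[j - 1] else mismatch)
            h, t = 0, 0
            if diag >= h:
                h, t = diag, 1
            if F[i][j] > h:
                h, t = F[i][j], 3
            if E[i][j] > h:
                h, t = E[i][j], 2
            H[i][j], TH[i][j] = h, t
            if h > best:
                best, bi, bj = h, i, j
    matches = mismatches = gaps = 0
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        if state == 0:
            t = TH[i][j]
            if t == 0:
                break
            if t == 1:
                if q[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            else:
                state = t
        elif state == 2:
            gaps += 1
            opened = TE[i][j]
            j -= 1
            state = 0 if opened else 2
        else:
            gaps += 1
            opened = TF[i][j]
            i -= 1
            state = 0 if opened else 3
    return best, matches, mismatches, gaps


def interval_union_oracle(intervals, min_ovl):
    """Fixpoint pairwise merging of half-open intervals overlapping >= min_ovl."""
    ivs = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for a in range(len(ivs)):
            for b in range(a + 1, len(ivs)):
                s = max(ivs[a][0], ivs[b][0])
                e = min(ivs[a][1], ivs[b][1])
                if e - s >= min_ovl:
                    ivs[a] = [min(ivs[a][0], ivs[b][0]), max(ivs[a][1], ivs[b][1])]
                    del ivs[b]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(iv) for iv in ivs)
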