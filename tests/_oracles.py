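"""Independent brute-force oracles used only by the test suite.

These re-derive the expected answers with plain Python loops and a different
algorithmic organisation from the package (no cumulative sums, no tabular
matrices), so agreement is a genuine cross-check.
"""

from __future__ import annotations

MISSING = -1


def brute_force_roh(calls, chroms, positions, *, window_snp=50, window_het_max=1,
                    window_missing_max=5, window_hit_fraction=0.05, min_snp=100,
                    min_length_bp=1_000_000, density_bp_per_snp=50_000,
                    max_gap_bp=1_000_000):
    """Enumerate ROH segments for one individual by exhaustive window counting.

    Returns (chrom, start_bp, end_bp, n_snps) tuples in position order.
    """
    out = []
    # group indices per chromosome preserving order
    seen = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    for chrom in seen:
        idx = [i for i, c in enumerate(chroms) if c == chrom]
        g = [calls[i] for i in idx]
        pos = [positions[i] for i in idx]
        n = len(g)
        w = window_snp
        # window verdicts by direct counting
        win_ok = []
        for s in range(n - w + 1):
            window = g[s:s + w]
            het = sum(1 for x in window if x == 1)
            mis = sum(1 for x in window if x == MISSING)
            win_ok.append(het <= window_het_max and mis <= window_missing_max)
        # per-SNP eligibility by direct enumeration of covering windows
        eligible = []
        for i in range(n):
            covering = [win_ok[s] for s in range(len(win_ok)) if s <= i <= s + w - 1]
            eligible.append(bool(covering) and
                            sum(covering) / len(covering) >= window_hit_fraction)
        # maximal eligible runs
        runs = []
        i = 0
        while i < n:
            if eligible[i]:
                j = i
                while j + 1 < n and eligible[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        # split at gaps, then trim het/missing ends of each piece
        for s0, e0 in runs:
            pieces = []
            a = s0
            for k in range(s0, e0):
                if pos[k + 1] - pos[k] > max_gap_bp:
                    pieces.append((a, k))
                    a = k + 1
            pieces.append((a, e0))
            for s, e in pieces:
                while s <= e and g[s] in (1, MISSING):
                    s += 1
                while e >= s and g[e] in (1, MISSING):
                    e -= 1
                if s > e:
                    continue
                n_snps = e - s + 1
                length = pos[e] - pos[s]
                if (n_snps >= min_snp and length >= min_length_bp
                        and length / n_snps <= density_bp_per_snp):
                    out.append((chrom, pos[s], pos[e], n_snps))
    return out


def kinship_f(parents):
    """Pedigree inbreeding via memoised kinship recursion.

    ``parents`` maps individual -> (sire | None, dam | None); individuals
    referenced only as parents are founders. Returns {individual: F}.
    F(x) = phi(sire, dam); phi(i,i) = (1 + F(i)) / 2;
    phi(i,j) = (phi(sire_i, j) + phi(dam_i, j)) / 2 with i the younger.
    """
    depth_memo = {}

    def depth(i):
        if i is None or i not in parents:
            return 0
        if i not in depth_memo:
            s, d = parents[i]
            depth_memo[i] = 1 + max(depth(s), depth(d))
        return depth_memo[i]

    memo = {}

    def phi(i, j):
        if i is None or j is None:
            return 0.0
        key = (i, j) if i <= j else (j, i)
        if key in memo:
            return memo[key]
        if i == j:
            s, d = parents.get(i, (None, None))
            val = 0.5 * (1.0 + phi(s, d))
        else:
            # recurse on the individual further from the founders
            if depth(i) < depth(j) or (depth(i) == depth(j) and i < j):
                i, j = j, i
            s, d = parents.get(i, (None, None))
            val = 0.5 * (phi(s, j) + phi(d, j))
        memo[key] = val
        return val

    out = {}
    for ind in parents:
        s, d = parents[ind]
        out[ind] = phi(s, d)
    return out
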