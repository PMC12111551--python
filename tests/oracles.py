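"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from the definitions, in a
different style from the library code: exact rational/decimal arithmetic
for the meta-analysis closed forms and the hypergeometric tail, and plain
step-by-step loops for greedy clumping and nearest-gene search.
"""

from __future__ import annotations

import math
from decimal import Decimal, localcontext
from fractions import Fraction


def _frac(x) -> Fraction:
    return Fraction(float(x))


def _dec_sqrt(f: Fraction) -> Decimal:
    with localcontext() as ctx:
        ctx.prec = 60
        return (Decimal(f.numerator) / Decimal(f.denominator)).sqrt()


def ivw_q_exact(beta_a, se_a, beta_b, se_b):
    """High-precision fixed-effect IVW combination and Cochran's Q.

    Returns ``(beta_meta, se_meta, z, q)`` as floats computed from exact
    rational arithmetic (square roots at 60 significant digits).
    """
    ba, bb = _frac(beta_a), _frac(beta_b)
    wa = 1 / _frac(se_a) ** 2
    wb = 1 / _frac(se_b) ** 2
    beta_meta = (wa * ba + wb * bb) / (wa + wb)
    se_meta = _dec_sqrt(1 / (wa + wb))
    with localcontext() as ctx:
        ctx.prec = 60
        z = (Decimal(beta_meta.numerator) / Decimal(beta_meta.denominator)) / se_meta
    q = wa * (ba - beta_meta) ** 2 + wb * (bb - beta_meta) ** 2
    return float(beta_meta), float(se_meta), float(z), float(q)


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    total = math.comb(N, n)
    upper = min(K, n)
    if k > upper:
        raise ValueError("k exceeds min(K, n)")
    acc = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(max(k, 0), upper + 1)
              if n - i <= N - K)
    return Fraction(acc, total)


def greedy_clump_reference(records, r2_of, r2_lead, merge_distance):
    """Step-by-step greedy clumping on a list of record dicts.

    ``records``: dicts with rsid, chrom, pos, p_meta and optionally
    mlog10_p_meta. ``r2_of(rs1, rs2)`` returns the LD r^2. Returns a list
    of clump dicts (lead, members, span) with a merged-region group id,
    ordered by (chrom, pos, lead).
    """
    if records and "mlog10_p_meta" in records[0]:
        pending = sorted(records, key=lambda r: (-r["mlog10_p_meta"],
                                                 r["pos"], r["rsid"]))
    else:
        pending = sorted(records, key=lambda r: (r["p_meta"], r["pos"], r["rsid"]))
    done = set()
    clumps = []
    for rec in pending:
        if rec["rsid"] in done:
            continue
        members = [rec["rsid"]]
        done.add(rec["rsid"])
        for other in pending:
            if other["rsid"] in done or other["chrom"] != rec["chrom"]:
                continue
            if r2_of(rec["rsid"], other["rsid"]) >= r2_lead:
                members.append(other["rsid"])
                done.add(other["rsid"])
        pos_of = {r["rsid"]: r["pos"] for r in records}
        clumps.append({
            "lead": rec["rsid"], "chrom": rec["chrom"], "pos": rec["pos"],
            "members": frozenset(members),
            "span": (min(pos_of[m] for m in members),
                     max(pos_of[m] for m in members)),
        })
    # merge spans within merge_distance on one chromosome
    group_id = 0
    for ch in sorted({c["chrom"] for c in clumps}):
        on_ch = sorted((c for c in clumps if c["chrom"] == ch),
                       key=lambda c: (c["span"][0], c["span"][1], c["lead"]))
        prev_end = None
        current = []
        for c in on_ch:
            if current and c["span"][0] - prev_end > merge_distance:
                lo = min(x["span"][0] for x in current)
                hi = max(x["span"][1] for x in current)
                for x in current:
                    x["locus"] = (group_id, lo, hi)
                group_id += 1
                current, prev_end = [], None
            current.append(c)
            prev_end = c["span"][1] if prev_end is None else max(prev_end, c["span"][1])
        if current:
            lo = min(x["span"][0] for x in current)
            hi = max(x["span"][1] for x in current)
            for x in current:
                x["locus"] = (group_id, lo, hi)
            group_id += 1
    return sorted(clumps, key=lambda c: (c["chrom"], c["pos"], c["lead"]))


def nearest_gene_bruteforce(pos, chrom, genes):
    """Linear scan over every gene row; ties by (distance, |pos-start|,
    symbol). ``genes`` is an iterable of dicts."""
    best = None
    for g in genes:
        if str(g["chrom"]) != str(chrom):
            continue
        if g["start"] <= pos <= g["end"]:
            d = 0
        else:
            d = min(abs(pos - g["start"]), abs(pos - g["end"]))
        key = (d, abs(pos - g["start"]), g["symbol"])
        if best is None or key < best[0]:
            best = (key, g, d)
    if best is None:
        return None, None
    return best[1], best[2]
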