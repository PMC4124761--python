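"""Independent brute-force oracles kept deliberately separate from the
implementation paths they check."""

from __future__ import annotations

from math import comb

from smallrna_sig.genome_match import Hit
from smallrna_sig.util import revcomp


def naive_scan(genome: dict[str, str], query: str) -> list[Hit]:
    """All perfect occurrences of ``query`` on both strands by sliding search.

    Same convention as the index: a '-' hit at ``start`` means the genome
    substring there equals the reverse complement of the query.
    """
    hits: list[Hit] = []
    rc = revcomp(query)
    for chrom, seq in genome.items():
        for probe, strand in ((query, "+"), (rc, "-")):
            if "N" in probe:
                continue
            start = seq.find(probe)
            while start != -1:
                hits.append(Hit(chrom, start, strand))
                start = seq.find(probe, start + 1)
    return sorted(hits)


def fisher_exact_p(table: list[list[int]]) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k: int) -> float:
        return comb(row1, k) * comb(n - row1, col1 - k) / comb(n, col1)

    p_obs = prob(a)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    return sum(p for k in range(lo, hi + 1)
               if (p := prob(k)) <= p_obs * (1 + 1e-9))
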