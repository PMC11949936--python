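"""Independent brute-force protospacer oracle used by the property tests.

Deliberately written without reference to the package implementation: it
slides a 23-bp window over every offset, tests the forward-strand PAM on
the window itself and the reverse-strand PAM on the window's reverse
complement, and records guides as plain tuples.
"""

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_RC[b] for b in reversed(seq))


def brute_force_scan(sequence, start, end, chrom="chr"):
    """All (spacer, pam, chrom, spacer_start, spacer_end, strand, cut_site)
    tuples for NGG protospacers fully inside [start, end)."""
    out = set()
    for i in range(start, end - 23 + 1):
        window = sequence[i : i + 23]
        if any(b not in "ACGT" for b in window):
            continue
        if window[-2:] == "GG":
            out.add((window[:20], window[20:], chrom, i, i + 20, "+", i + 17))
        rev = rc(window)
        if rev[-2:] == "GG":
            # protospacer on the minus strand: spacer occupies the high
            # 20 bp of the forward window, PAM the low 3 bp
            out.add((rev[:20], rev[20:], chrom, i + 3, i + 23, "-", i + 6))
    return out


def library_as_tuples(lib):
    return {
        (g.spacer, g.pam, g.chrom, g.spacer_start, g.spacer_end, g.strand, g.cut_site)
        for g in lib.guides
    }
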