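"""Small sequence helpers shared across modules."""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmers_of(seq: str, k: int):
    """Yield (offset, kmer) for every N-free k-mer of ``seq``."""
    n = len(seq)
    for i in range(n - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            yield i, km
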