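"""Independent re-implementations used as oracles by multiple test modules."""


def brute_force_greedy_bins(ids, r2, maf, r2_tag):
    """Greedy pairwise tag binning, written independently of the library.

    ``r2`` is a nested list indexed by position in ``ids``; ties break by
    higher MAF then lower position, as documented for the library routine.
    """
    order = {v: k for k, v in enumerate(ids)}
    untagged = set(ids)
    bins = {}
    while untagged:
        candidates = []
        for v in untagged:
            cover = frozenset(
                w for w in untagged if w == v or r2[order[v]][order[w]] >= r2_tag
            )
            candidates.append((len(cover), maf[v], -order[v], v, cover))
        candidates.sort(reverse=True)
        _, _, _, tag, cover = candidates[0]
        bins[tag] = sorted(cover, key=lambda w: order[w])
        untagged -= cover
    return bins
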