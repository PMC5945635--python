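"""Brute-force shared-cluster oracle, independent of the implementation path."""

from mitobipart.gene_order import GeneOrder, normalize_gene_name


def brute_force_clusters(order_a: GeneOrder, order_b: GeneOrder) -> set:
    """Enumerate every contiguous block (wrapping circular origins) of each
    order, intersect, and keep the strictly maximal gene strings — blocks not
    contained as a contiguous substring of any longer common block
    (full-circle blocks are containers up to rotation)."""

    def blocks(order):
        sg = order.normalized()
        n = len(sg)
        out = set()
        for i in range(n):
            for L in range(2, n + 1):
                if not order.circular and i + L > n:
                    break
                out.add(tuple(sg[(i + t) % n] for t in range(L)))
        return out

    cap = min(len(order_a.genes), len(order_b.genes))
    both_circular = order_a.circular and order_b.circular
    common = blocks(order_a) & blocks(order_b)

    def contained(short, long):
        if len(short) >= len(long):  # equal length: rotations merge later, not here
            return False
        hay = long * 2 if (both_circular and len(long) == cap) else long
        return any(hay[k : k + len(short)] == short for k in range(len(hay) - len(short) + 1))

    maximal = {blk for blk in common if not any(contained(blk, other) for other in common)}
    # full-circle blocks are one cluster up to rotation: canonicalize
    out = set()
    for blk in maximal:
        if both_circular and len(blk) == cap:
            blk = min(tuple(blk[k:] + blk[:k]) for k in range(len(blk)))
        out.add(blk)
    return out


def impl_keys(clusters, order_a, order_b):
    """Implementation clusters as normalized tuples, canonicalized like the oracle."""
    cap = min(len(order_a.genes), len(order_b.genes))
    both_circular = order_a.circular and order_b.circular
    keys = set()
    for c in clusters:
        blk = tuple((normalize_gene_name(g), 1) for g in c.genes)
        if both_circular and len(blk) == cap:
            blk = min(tuple(blk[k:] + blk[:k]) for k in range(len(blk)))
        keys.add(blk)
    return keys
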