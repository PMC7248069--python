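"""Independent oracles for the test suite.

These deliberately avoid the package's simulation code paths: outcomes of a
single chromosome passing through meiosis are enumerated exhaustively over
the finite tree of equally likely segregation choices, so that empirical
frequencies from the simulator can be checked against exact probabilities.
"""

from collections import defaultdict
from itertools import product


def enumerate_one_chromosome(
    p_bivalent: float, p_pssc: float, p_mii_ndj: float
) -> dict[tuple[int, int, int, int], float]:
    """Exact outcome distribution for one chromosome through MI and MII.

    Returns a map (egg_dyads, egg_singles, zygote_maternal_chromatids,
    pb2_chromatids) -> probability.  The tree: the chromosome is a bivalent
    with probability p_bivalent (one dyad each to egg and PB1), else two
    univalents, each prematurely separated with probability p_pssc; intact
    univalents and free chromatids segregate to the egg with probability 1/2
    each; at MII each egg dyad nondisjoins with probability p_mii_ndj (both
    chromatids to one product, either with probability 1/2), otherwise
    splits 1+1, and each egg single goes to either product with probability
    1/2.
    """
    dist: dict[tuple[int, int, int, int], float] = defaultdict(float)

    prophase = []
    if p_bivalent > 0:
        prophase.append((p_bivalent, None))
    if p_bivalent < 1:
        for s1, s2 in product((False, True), repeat=2):
            pr = (1 - p_bivalent)
            pr *= p_pssc if s1 else 1 - p_pssc
            pr *= p_pssc if s2 else 1 - p_pssc
            if pr > 0:
                prophase.append((pr, (s1, s2)))

    for p_pro, seps in prophase:
        # MI: list of (prob, egg_dyads, egg_singles)
        if seps is None:
            mi_outcomes = {(1, 0): 1.0}
        else:
            # one segregating item per intact univalent ('d') and per free
            # chromatid of a separated univalent ('c')
            items = []
            for sep in seps:
                items.extend("cc" if sep else "d")
            mi_outcomes: dict[tuple[int, int], float] = defaultdict(float)
            for assign in product((0, 1), repeat=len(items)):
                d = sum(1 for it, a in zip(items, assign) if it == "d" and a)
                s = sum(1 for it, a in zip(items, assign) if it == "c" and a)
                mi_outcomes[(d, s)] += 0.5 ** len(items)

        for (egg_d, egg_s), p_mi in mi_outcomes.items():
            # MII: each dyad -> (1,1) w.p. 1-ndj, (2,0) or (0,2) w.p. ndj/2
            dyad_moves = [(1 - p_mii_ndj, 1, 1), (p_mii_ndj / 2, 2, 0), (p_mii_ndj / 2, 0, 2)]
            single_moves = [(0.5, 1, 0), (0.5, 0, 1)]
            partials = {(0, 0): 1.0}
            for moves, count in ((dyad_moves, egg_d), (single_moves, egg_s)):
                for _ in range(count):
                    nxt: dict[tuple[int, int], float] = defaultdict(float)
                    for (z, b), pp in partials.items():
                        for pm, dz, db in moves:
                            if pm > 0:
                                nxt[(z + dz, b + db)] += pp * pm
                    partials = nxt
            for (z, b), p_mii in partials.items():
                dist[(egg_d, egg_s, z, b)] += p_pro * p_mi * p_mii
    return dict(dist)


def one_chromosome_truth_relation(
    zygote_units_total: int, pb2_units: int
) -> str:
    """Karyotype-level relation for one chromosome of a matched pair.

    The zygote is aneuploid when its total chromatid units (maternal plus the
    one paternal chromatid) differ from 2; the polar body when its units
    differ from 1.  Relations follow the call-comparison rules.
    """
    z = (zygote_units_total > 2) - (zygote_units_total < 2)
    p = (pb2_units > 1) - (pb2_units < 1)
    if z == 0 and p == 0:
        return "neutral"
    if z == 0 or p == 0:
        return "unmatched"
    return "reciprocal" if z != p else "concordant"
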