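import numpy as np
import pytest
from hypothesis import settings

from nucpattern.geometry import build_gbs_map

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

WW = {"AA", "AT", "TA", "TT"}
SS = {"CC", "CG", "GC", "GG"}


@pytest.fixture(scope="session")
def gbs_map():
    return build_gbs_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng, n, gc=0.5):
    return "".join(rng.choice(list("ACGT"), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))


def naive_site_counts(sequence, gbs_map):
    """Independent oracle: scan all dinucleotide positions, test site membership."""
    counts = {"ww_minor": 0, "ww_major": 0, "ss_minor": 0, "ss_major": 0}
    for i in range(len(sequence) - 1):
        dinuc = sequence[i : i + 2]
        if dinuc in WW:
            cls = "ww"
        elif dinuc in SS:
            cls = "ss"
        else:
            continue
        for site in gbs_map.sites:
            # both bases must lie inside the site
            if site.start <= i and i + 1 <= site.end - 1:
                counts[f"{cls}_{site.groove}"] += 1
    return counts


def brute_force_pairs(sequence, class_a, class_b, max_d, symmetric):
    """Independent oracle: enumerate all occurrence pairs with a double loop."""
    ref = {"WW": WW, "SS": SS}
    pieces, cur = [], []
    for ch in sequence:
        if ch in "ACGT":
            cur.append(ch)
        else:
            pieces.append("".join(cur))
            cur = []
    pieces.append("".join(cur))
    counts = np.zeros(max_d, dtype=int)
    for piece in pieces:
        a_pos = [i for i in range(len(piece) - 1) if piece[i : i + 2] in ref[class_a]]
        b_pos = [i for i in range(len(piece) - 1) if piece[i : i + 2] in ref[class_b]]
        for i in a_pos:
            for j in b_pos:
                d = j - i
                if 1 <= d <= max_d:
                    counts[d - 1] += 1
                if symmetric and class_a != class_b and 1 <= -d <= max_d:
                    counts[-d - 1] += 1
    return counts
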