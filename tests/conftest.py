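import numpy as np
import pytest

#: Nine validated surrogate peptides (one per marker protein panel entry).
TABLE1_PEPTIDES = [
    "TPDVSSALDK",    # APOC1
    "VIAVNEVGR",     # CHL1
    "AVIDDAFAR",     # MMP9
    "STTPDITGYR",    # FN1
    "ILAGPAGDSNVVK", # VWF
    "LSILYPATTGR",   # PRDX6
    "TTSGIHPK",      # PPBP
    "AIGPSQTHTIR",   # PRG4
    "TLLSNLEEAK",    # CLU
]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_digest(sequence: str) -> list[tuple[int, int]]:
    """Independent tryptic-digestion oracle: test every substring.

    A substring s[i:j] is a fully tryptic product (zero missed
    cleavages) iff its left boundary is the protein start or a valid
    cleavage point (K/R before it, no following P), it ends in K/R with
    the next residue (if any) not P, and no valid cleavage point lies
    strictly inside it.
    """
    n = len(sequence)
    out = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            left_ok = i == 0 or (
                sequence[i - 1] in "KR" and sequence[i] != "P"
            )
            right_ok = sequence[j - 1] in "KR" and (
                j == n or sequence[j] != "P"
            )
            if not (left_ok and right_ok):
                continue
            internal = any(
                sequence[k - 1] in "KR" and sequence[k] != "P"
                for k in range(i + 1, j)
            )
            if not internal:
                out.append((i, j))
    return sorted(out)


def pair_counting_auc(scores, labels) -> float:
    """Independent AUC oracle: concordant pairs + half ties over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)
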