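"""Independent brute-force oracles used by the test suite.

Deliberately avoids numpy vector operations so the re-derivations are
independent of the implementation paths they check.
"""

from collections import Counter

from breathcal import FeatureVector


def brute_force_features(readings) -> FeatureVector:
    """Counter/loop-based re-derivation of the seven signal features."""
    w = [float(x) for x in list(readings)[:30]]
    first10, first20 = w[:10], w[:20]
    counts = Counter(first10)
    top = max(counts.values())
    mode10 = max(v for v, c in counts.items() if c == top)  # largest modal value
    max30, min30 = max(w), min(w)
    avg20 = sum(first20) / 20
    avg30 = sum(w) / 30
    return FeatureVector(
        mode10, max30, min30, avg20, avg30, max30 - avg20, max30 - avg30
    )
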