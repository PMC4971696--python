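"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations


def brute_force_first_index(
    rule_id: str,
    measured,
    underlying=None,
    threshold: float = 140.0,
) -> int:
    """Earliest diagnosing visit by literal enumeration of every window and
    exceedance count; -1 if never diagnosed.  Deliberately naive."""
    m = list(measured)
    u = list(underlying) if underlying is not None else None
    for k in range(len(m)):
        if rule_id == "single":
            hit = m[k] > threshold
        elif rule_id == "two_consecutive":
            hit = k >= 1 and m[k - 1] > threshold and m[k] > threshold
        elif rule_id == "mean_two":
            hit = k >= 1 and (m[k - 1] + m[k]) / 2.0 > threshold
        elif rule_id == "any_three":
            hit = m[k] > threshold and sum(v > threshold for v in m[: k + 1]) >= 3
        elif rule_id == "mean_three":
            hit = k >= 2 and (m[k - 2] + m[k - 1] + m[k]) / 3.0 > threshold
        elif rule_id == "oracle":
            hit = m[k] > threshold and u[k] > threshold
        else:
            raise ValueError(rule_id)
        if hit:
            return k
    return -1
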