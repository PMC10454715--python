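"""Independent transcription of the 2015 evidence-combining rules, kept
deliberately separate (rule-list style) from the package implementation so
the two routes can be compared over an exhaustive enumeration."""

from acmgvus.model import StrengthCounts

# Each rule is one clause of the published combining scheme.
PATHOGENIC_RULES = (
    lambda c: c.pvs >= 1 and c.ps >= 1,
    lambda c: c.pvs >= 1 and c.pm >= 2,
    lambda c: c.pvs >= 1 and c.pm >= 1 and c.pp >= 1,
    lambda c: c.pvs >= 1 and c.pp >= 2,
    lambda c: c.ps >= 2,
    lambda c: c.ps >= 1 and c.pm >= 3,
    lambda c: c.ps >= 1 and c.pm >= 2 and c.pp >= 2,
    lambda c: c.ps >= 1 and c.pm >= 1 and c.pp >= 4,
)

LIKELY_PATHOGENIC_RULES = (
    lambda c: c.pvs >= 1 and c.pm >= 1,
    lambda c: c.ps >= 1 and c.pm >= 1,
    lambda c: c.ps >= 1 and c.pp >= 2,
    lambda c: c.pm >= 3,
    lambda c: c.pm >= 2 and c.pp >= 2,
    lambda c: c.pm >= 1 and c.pp >= 4,
)

BENIGN_RULES = (
    lambda c: c.ba >= 1,
    lambda c: c.bs >= 2,
)

LIKELY_BENIGN_RULES = (
    lambda c: c.bs >= 1 and c.bp >= 1,
    lambda c: c.bp >= 2,
)


def oracle_acmg(counts: StrengthCounts) -> str:
    """Brute-force verdict: strongest matching rule per side; conflicting
    sides (or no match) give VUS."""
    p = any(rule(counts) for rule in PATHOGENIC_RULES)
    lp = any(rule(counts) for rule in LIKELY_PATHOGENIC_RULES)
    b = any(rule(counts) for rule in BENIGN_RULES)
    lb = any(rule(counts) for rule in LIKELY_BENIGN_RULES)
    if (p or lp) and (b or lb):
        return "VUS"
    if p:
        return "P"
    if lp:
        return "LP"
    if b:
        return "B"
    if lb:
        return "LB"
    return "VUS"
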