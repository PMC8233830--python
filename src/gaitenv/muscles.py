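"""Canonical muscle and walking-environment vocabularies.

Eleven lower-extremity muscles are recorded: rectus femoris (RF), vastus
lateralis/medialis (VL, VM), semitendinosus (ST), biceps femoris (BF),
tibialis anterior (TA), soleus (Sol), medial/lateral gastrocnemius (MG, LG),
flexor hallucis longus (FHL) and extensor digitorum longus (EDL).  All
concatenated profile vectors use the fixed canonical order below, whatever
order channels arrive in on disk.
"""

from __future__ import annotations

# Fixed canonical channel order; every profile concatenation uses it.
CANONICAL_MUSCLES: tuple[str, ...] = (
    "RF", "VL", "VM", "ST", "BF", "TA", "Sol", "MG", "LG", "FHL", "EDL",
)

_MUSCLE_INDEX = {m: i for i, m in enumerate(CANONICAL_MUSCLES)}

# Walking environments: flat-ground, upstairs, downstairs, uphill, downhill.
ENVIRONMENTS: tuple[str, ...] = ("FGW", "US", "DS", "UW", "DW")

# Integer class labels used by the classifier (FGW=1 ... DW=5).
ENV_LABELS: dict[str, int] = {env: i + 1 for i, env in enumerate(ENVIRONMENTS)}
LABEL_ENVS: dict[int, str] = {v: k for k, v in ENV_LABELS.items()}

# Per-joint flexor/extensor groupings (anatomical convention: the hamstrings
# ST/BF flex the knee, the quadriceps VL/VM/RF extend it; TA dorsiflexes the
# ankle, the triceps surae Sol/MG/LG plantarflex it).
MUSCLE_GROUPS: dict[str, tuple[str, ...]] = {
    "knee_flexors": ("ST", "BF"),
    "knee_extensors": ("VL", "VM", "RF"),
    "ankle_flexor": ("TA",),
    "ankle_extensors": ("Sol", "MG", "LG"),
    "mtp_flexor": ("FHL",),
    "mtp_extensor": ("EDL",),
}


class UnknownMuscleError(ValueError):
    """A channel name is not one of the eleven canonical muscles."""

    def __init__(self, name: str):
        super().__init__(
            f"unknown muscle name {name!r}; expected one of "
            f"{', '.join(CANONICAL_MUSCLES)}"
        )
        self.name = name


def validate_muscles(names) -> tuple[str, ...]:
    """Check every name against the canonical set; returns them unchanged."""
    names = tuple(names)
    for n in names:
        if n not in _MUSCLE_INDEX:
            raise UnknownMuscleError(n)
    return names


def canonical_sort(names) -> tuple[str, ...]:
    """Return the given muscles sorted into canonical order (duplicates dropped)."""
    names = validate_muscles(names)
    return tuple(sorted(set(names), key=_MUSCLE_INDEX.__getitem__))


def validate_environment(env: str) -> str:
    if env not in ENV_LABELS:
        raise ValueError(
            f"unknown environment {env!r}; expected one of {', '.join(ENVIRONMENTS)}"
        )
    return env
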