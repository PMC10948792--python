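"""Fixed emotion-category vocabulary and rating scales.

The default category list is the thirteen emotions used throughout the
analyses, in their canonical (alphabetical) order.  All tables and priors
echo whatever ordered list they were built with, so alternative category
sets can be supplied anywhere a ``emotions`` argument appears.
"""

EMOTIONS: tuple[str, ...] = (
    "amusement",
    "anger",
    "awe",
    "contempt",
    "disgust",
    "embarrassment",
    "fear",
    "happiness",
    "interest",
    "pride",
    "sadness",
    "shame",
    "surprise",
)

#: Ordinal encoding of the presence-gated 4-point intensity scale.
#: 0 is reserved for "emotion absent"; 1..4 are the present-intensity anchors.
INTENSITY_FROM_LABEL: dict[str, int] = {
    "absent": 0,
    "slightly": 1,
    "moderately": 2,
    "strongly": 3,
    "intensely": 4,
}

INTENSITY_MIN, INTENSITY_MAX = 0, 4

#: 7-point likelihood scale used by the priors task (1 = not at all likely,
#: 4 = moderately likely, 7 = extremely likely).
PRIOR_LIKELIHOOD_MIN, PRIOR_LIKELIHOOD_MAX = 1, 7

CONDITIONS: tuple[str, ...] = ("face_only", "situation_only", "joint")

QUALITIES: tuple[str, ...] = ("valid", "accidental", "incorrect", "missing")

MODEL_NAMES: tuple[str, ...] = ("face", "situation", "integration")
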