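"""The four rhythm classes and their canonical ordering.

SB   -- sinus bradycardia
AFIB -- atrial fibrillation
GSVT -- supraventricular tachycardia group
SR   -- sinus rhythm
"""

CLASSES = ("SB", "AFIB", "GSVT", "SR")
LABEL_TO_INDEX = {c: i for i, c in enumerate(CLASSES)}
N_CLASSES = len(CLASSES)


def label_index(label: str) -> int:
    try:
        return LABEL_TO_INDEX[label]
    except KeyError:
        raise ValueError(
            f"unknown rhythm label {label!r}; valid labels are {CLASSES}"
        ) from None
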