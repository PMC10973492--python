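"""Reference cohort: fatty-liver grade counts after quality control.

The published abdominal-ultrasound cohort this package's splitting
arithmetic is checked against contains 16,772 subjects after excluding
uncertain labels, graded normal / mild / moderate / severe. The three
classification tasks coarsen the grades: two-class (normal vs any
disease), three-class (normal / mild / moderate+severe) and four-class
(all grades). These counts are inputs to the balanced-split arithmetic;
the images themselves are access-controlled and are not used here.
"""

from __future__ import annotations

COHORT_CLASS_COUNTS = {
    "normal": 12_321,
    "mild": 2_287,
    "moderate": 1_629,
    "severe": 535,
}

COHORT_TOTAL = sum(COHORT_CLASS_COUNTS.values())


def task_class_counts(n_classes: int) -> dict[str, int]:
    """Per-class subject counts for the 2-, 3- or 4-class task."""
    c = COHORT_CLASS_COUNTS
    if n_classes == 2:
        return {"normal": c["normal"],
                "disease": c["mild"] + c["moderate"] + c["severe"]}
    if n_classes == 3:
        return {"normal": c["normal"], "mild": c["mild"],
                "moderate+severe": c["moderate"] + c["severe"]}
    if n_classes == 4:
        return dict(c)
    raise ValueError("n_classes must be 2, 3 or 4")
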