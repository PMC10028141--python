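"""Published counts from the college-student childhood-trauma cohort that the
package's defaults emulate.

These constants are regression fixtures for the descriptive-statistics
layer: prevalence of the three abuse subgroups among the screened
students, the sociodemographic contingency tables, and per-group scale
summaries (mean, SD) for the three instruments.  Columns of every
contingency table are the EA, PA, SA subgroups in that order.
"""

from __future__ import annotations

#: students completing the screen
TOTAL_SCREENED = 96_218

#: subgroup sizes (moderate-severe emotional, physical, sexual abuse)
GROUP_SIZES = {"EA": 1_191, "PA": 1_272, "SA": 3_479}

#: rows = female / male
SEX_TABLE = [
    [856, 528, 1780],
    [335, 744, 1699],
]

#: rows = study years 1-4
EDUCATION_TABLE = [
    [558, 608, 1626],
    [323, 356, 915],
    [181, 183, 566],
    [129, 125, 372],
]

#: rows = city / town-and-county
RESIDENCE_TABLE = [
    [673, 709, 1788],
    [518, 563, 1691],
]

#: rows = Han / other ethnicity
ETHNICITY_TABLE = [
    [1057, 1127, 3119],
    [134, 145, 360],
]

#: rows = nuclear / three-generation / adoptive / reconstituted /
#: single-parent / left-behind family
FAMILY_TYPE_TABLE = [
    [644, 798, 2272],
    [173, 238, 651],
    [6, 1, 6],
    [91, 59, 119],
    [223, 149, 357],
    [54, 27, 74],
]

#: rows = four annual-income brackets (ascending)
INCOME_TABLE = [
    [375, 373, 1052],
    [406, 395, 1047],
    [168, 224, 553],
    [242, 280, 827],
]

#: rows = only child yes / no
ONLY_CHILD_TABLE = [
    [572, 620, 1698],
    [619, 652, 1781],
]

#: per-group scale totals: (mean, sd) keyed by group, per instrument
SCALE_SUMMARIES = {
    "PHQ9": {"EA": (11.25, 6.35), "PA": (7.92, 5.19), "SA": (6.91, 4.92)},
    "GAD7": {"EA": (8.54, 5.62), "PA": (5.74, 4.56), "SA": (5.18, 4.34)},
    "TSQ": {"EA": (6.10, 2.91), "PA": (4.45, 3.05), "SA": (4.32, 3.14)},
}
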