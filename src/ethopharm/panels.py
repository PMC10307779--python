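"""Canonical outcome-measure names, shared by the generator and the
measure-derivation and clustering modules.

The eight pre-surgery measures quantify thermal reflex pain and its change
over sessions, basal and habituating vehicle locomotion, acute and
sensitizing oxycodone locomotion, and conditioned place preference and its
extinction.  The six post-surgery measures quantify reflex pain in the
surgeried paw (absolute, relative to the other paw, and relative to
baseline) and post-surgery CPP relative to three earlier reference tests.
"""

PRE_MEASURES = (
    "Basal reflex pain",
    "Rate of change in reflex pain",
    "Basal loco",
    "Rate of loco habituation",
    "Acute OXY loco",
    "Rate of behavioral sensitization",
    "CPP at first test",
    "Rate of CPP extinction",
)

POST_MEASURES = (
    "Reflex pain–surg. paw",
    "Reflex pain–surg. paw vs. non-surg. paw",
    "Reflex pain–Δ surg. paw",
    "CPP–Δ pre-test CPP",
    "CPP–Δ post-cond. CPP",
    "CPP–Δ pre-surg. CPP",
)

ALL_MEASURES = PRE_MEASURES + POST_MEASURES
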