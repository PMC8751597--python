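"""Canonical catalogue of the 33 daily-activity variables.

Engagement in each activity is self-reported on an ordered frequency scale
("never" ... "daily") that the survey instrument discretises into six or
seven ordered categories.  Codes are stored 0..K-1.  The canonical names
below are the pipeline's internal keys; arbitrary export column names are
mapped onto them through the ingestion schema.
"""

from __future__ import annotations

# name -> number of ordered categories (6 or 7)
ACTIVITY_CATEGORIES: dict[str, int] = {
    "CARE ADULT": 6,
    "DO ACTIVITIES WITH GRANDCHILDREN": 7,
    "VOLUNTEER YOUTH": 6,
    "CHARITY WORK": 6,
    "EDUCATION ACTIVITY": 6,
    "ATTEND SPORTS/SOCIAL/CLUB": 7,
    "ATTEND NON RELIGIOUS ORGS": 6,
    "PRAY PRIVATELY": 7,
    "READ": 7,
    "WATCH TELEVISION": 7,
    "DO WORD GAMES": 7,
    "PLAY CARDS AND GAMES": 7,
    "DO WRITING": 6,
    "USE COMPUTER": 7,
    "MAINTENANCE/GARDENING": 7,
    "BAKE OR COOK": 7,
    "SEW OR KNIT": 6,
    "DO HOBBY": 7,
    "PLAY SPORT/EXERCISE": 7,
    "WALK FOR 20 MINS": 7,
    "PARTICIPATE COMMUNITY ARTS GRP": 6,
    "MEET UP WITH CHILDREN": 7,
    "SPEAK ON PHONE WITH CHILDREN": 7,
    "WRITE OR EMAIL CHILDREN": 6,
    "COMMUNICATE BY SOCIAL MEDIA": 6,
    "MEET UP WITH OTHER FAMILY MEMBERS": 7,
    "SPEAK ON PHONE WITH OTHER FAMILY MEMBERS": 7,
    "WRITE OR EMAIL OTH FAMILY MEMBERS": 6,
    "COMMUNICATE BY SOCIAL MEDIA WITH FAMILY MEMBERS": 6,
    "MEET UP WITH FRIENDS": 7,
    "SPEAK ON PHONE WITH FRIENDS": 7,
    "WRITE OR EMAIL FRIENDS": 6,
    "COMMUNICATE BY SOCIAL MEDIA WITH FRIENDS": 6,
}

ACTIVITY_NAMES: tuple[str, ...] = tuple(ACTIVITY_CATEGORIES)

N_ACTIVITIES = len(ACTIVITY_NAMES)
assert N_ACTIVITIES == 33

# Non-activity predictors that always enter the stage-2 model.
EDUCATION = "EDUCATION_YEARS"
BASELINE_MEMORY = "BASELINE_MEMORY"
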