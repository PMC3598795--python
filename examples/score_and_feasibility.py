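"""Score respondents on the 0-100 scale and apply the missing-data rules.

Builds a tiny 3-respondent table by hand to show the reverse transform
(0 -> 100 ... 4 -> 0), the subscale mean over answered items, and the
more-than-half-missing rule that withholds a score.
"""

import numpy as np
import pandas as pd

from psychfield import load_instrument, score_dataset
from psychfield.dataset import ResponseDataset

spec = load_instrument("pedsql_nf1_adult")

raw = pd.DataFrame(0.0, index=["healthy", "burdened", "skipper"], columns=list(spec.item_ids))
raw.loc["burdened"] = 4.0
pain = list(spec.subscale("Pain and Hurt").item_ids)
raw.loc["skipper", pain] = [2.0, np.nan, np.nan]  # 2 of 3 pain items skipped

table = score_dataset(raw_ds := ResponseDataset(raw=raw), spec)
cols = ["Pain and Hurt", "Daily Activities", "Total Score"]
print(table.scores[cols].to_string())
print(
    "\n'healthy' answered 0 (never a problem) everywhere -> 100 on every "
    "scale; 'burdened' answered 4 -> 0.  'skipper' skipped 2 of 3 pain "
    "items: more than half missing, so that subscale score is withheld "
    "(NaN) while everything else is computed."
)
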