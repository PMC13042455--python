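"""Subset/condition preference via the Ro/e observed-over-expected ratio.

Expected counts come from the chi-square independence model; Ro/e > 1 marks
a subset over-represented in a condition.
"""

import pandas as pd

from tcrdyn import roe

counts = pd.DataFrame(
    {
        "PCR_post": [120, 30, 60],
        "nonMPR_post": [40, 90, 60],
    },
    index=["c05_CD8_Tem-GZMA", "c03_CD4_Treg-FOXP3", "c01_CD4_Tn-CCR7"],
)

result = roe(counts)
print(result.long_format().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# CD8 Tem cells are enriched in the responder condition (Ro/e > 1) while
# Tregs prefer the nonresponder condition; the naive subset is balanced.
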