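"""Score QUEST satisfaction records.

QUEST (Quebec User Evaluation of Satisfaction with Assistive Technology)
device subscale: eight items scored 1-5, summarized as their mean rounded
half-up to one decimal.  The two records below are a printed-orthosis and
a conventional-orthosis assessment of the same wearer.
"""

from afogen import QuestRecord, quest_total
from afogen.evaluation import QUEST_ITEMS

printed = QuestRecord.from_scores([4, 5, 4, 5, 5, 5, 4, 4])
conventional = QuestRecord.from_scores([4, 3, 5, 5, 5, 2, 4, 5])

print(f"{'item':>14s}  printed  conventional")
for item, a, b in zip(QUEST_ITEMS, printed.scores(), conventional.scores()):
    print(f"{item:>14s}  {a:^7d}  {b:^12d}")
print(f"{'total':>14s}  {quest_total(printed):^7.1f}  {quest_total(conventional):^12.1f}")
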