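"""The 243-trial deadline design and its counterbalancing.

Each participant answers all 27 queries in each of three domains, once per
response deadline (6, 9, 20 s).  Structure-domain pairing and deadline order
cycle through a balanced Latin-square scheme.
"""

from collections import Counter

from causalpress import assign_counterbalance, build_participant_design

assignment = assign_counterbalance(participant_id=4, scheme_seed=0)
print("Participant 4 counterbalance slot:")
for domain, structure in assignment.structure_by_domain:
    print(f"  {domain:<12} -> {structure.value}")
print(f"  deadline order per domain: {assignment.deadline_order_by_domain}")

design = build_participant_design(assignment, shuffle_seed=0)
print(f"\ntrials: {len(design)} "
      f"({design['domain'].nunique()} domains x "
      f"{design['deadline_s'].nunique()} deadlines x 27 queries)")
blocks = design.groupby(["domain", "deadline_s"]).size()
print(f"per-block trial count: {sorted(set(blocks))} (27 everywhere)")

pairings = Counter(
    assign_counterbalance(pid).structure_by_domain for pid in range(18)
)
print(f"\nover 18 consecutive participants each structure-domain bijection "
      f"appears {sorted(set(pairings.values()))} times (balanced).")
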