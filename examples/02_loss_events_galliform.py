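"""Cluster shared inactivating mutations into independent loss events.

Loads the galliform worked example (twelve species with catalogued
disruptions on a time-calibrated tree) and groups species that share an
identical mutation into one Dollo event on the stem of their clade.
"""

from genedecay.event_inference import infer_loss_events, label_branches, MIXED
from genedecay.synthetic_data import make_fixture

fixture = make_fixture("galliform")
events = infer_loss_events(
    fixture.tree, fixture.catalogs, reference=fixture.reference
)

print(f"disrupted species: {len(fixture.catalogs)}")
print(f"independent loss events: {len(events)}")
for event in events:
    members = ", ".join(sorted(event.species))
    shared = len(event.shared_mutations)
    print(f"  {event.event_id}: {members}" + (f"  [{shared} shared mutations]" if shared else ""))

labeled = label_branches(fixture.tree, events)
n_mixed = sum(1 for v in labeled.labels.values() if v == MIXED)
print(f"mixed (functional+pseudogenic) branches: {n_mixed}")

# Twelve disrupted species collapse to eight events: the two peafowls share
# two deletions, and the four grouse-clade species share one 13-base deletion.
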