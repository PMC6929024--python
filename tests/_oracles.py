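"""Independent brute-force oracles shared across test modules."""

import itertools

from pharmens.core import Pharmacophore
from pharmens.hashing import hash_pharmacophore
from pharmens.screening import ConformerRecord


def record_from_features(features, cid="C", sid="1", conf_id=0):
    return ConformerRecord(cid, sid, conf_id, [], list(features))


def oracle_match(record, model, cfg):
    """Exhaustive oracle: try every injective label-preserving mapping and
    test hash equality of the selected conformer subset."""
    target = hash_pharmacophore(model, cfg).digest
    by_label = {}
    for j, f in enumerate(record.features):
        by_label.setdefault(f.label, []).append(j)
    pools = [by_label.get(f.label, []) for f in model.features]
    if any(not p for p in pools):
        return False
    for combo in itertools.product(*pools):
        if len(set(combo)) != len(combo):
            continue
        feats = [record.features[j] for j in sorted(set(combo))]
        try:
            sub = Pharmacophore(feats)
        except ValueError:
            continue
        if hash_pharmacophore(sub, cfg).digest == target:
            return True
    return False
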