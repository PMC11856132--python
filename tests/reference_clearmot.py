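"""Independent reference implementation of the CLEAR-MOT metrics.

Written from the metric definitions alone, sharing no code with the
package: rectangle overlap is recomputed from corner arithmetic and the
per-frame correspondence is found by exhaustive search over all injective
gt→hypothesis mappings (feasible for the small frames used in tests),
maximising match count and breaking ties by maximum total overlap.  Serves
as the oracle the package implementation is checked against.
"""

from itertools import permutations


def rect_iou(a, b):
    # a, b: (left, top, width, height)
    ax1, ay1, ax2, ay2 = a[0], a[1], a[0] + a[2], a[1] + a[3]
    bx1, by1, bx2, by2 = b[0], b[1], b[0] + b[2], b[1] + b[3]
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def _best_injection(gt_items, hyp_items, threshold):
    """Exhaustive max-cardinality, max-total-IoU matching of index pairs."""
    n_g, n_h = len(gt_items), len(hyp_items)
    best = []
    best_key = (-1, -1.0)
    if n_g == 0 or n_h == 0:
        return best
    k = min(n_g, n_h)
    # choose which gt indices participate and in what hyp order
    from itertools import combinations

    for g_sub in combinations(range(n_g), k):
        for h_perm in permutations(range(n_h), k):
            pairs = []
            total = 0.0
            for gi, hj in zip(g_sub, h_perm):
                v = rect_iou(gt_items[gi][1], hyp_items[hj][1])
                if v >= threshold:
                    pairs.append((gi, hj, v))
                    total += v
            key = (len(pairs), total)
            if key > best_key:
                best_key, best = key, pairs
    return best


def reference_clearmot(gt_frames, hyp_frames, threshold=0.5):
    """gt_frames/hyp_frames: list (per frame) of lists of (identity, rect).

    Returns dict with mota (percent), motp (percent mean overlap), ids, fp,
    fn, gt totals.  Correspondence keeps previous-frame pairs that still
    overlap >= threshold, then exhaustively matches the rest.
    """
    assert len(gt_frames) == len(hyp_frames)
    fn = fp = ids = gt_total = 0
    overlap_sum = 0.0
    n_matches = 0
    prev_pair = {}
    last_match = {}
    for gt_items, hyp_items in zip(gt_frames, hyp_frames):
        gt_total += len(gt_items)
        gt_rest = list(range(len(gt_items)))
        hyp_rest = list(range(len(hyp_items)))
        matched = []
        for gi in list(gt_rest):
            g_id = gt_items[gi][0]
            want = prev_pair.get(g_id)
            if want is None:
                continue
            for hj in hyp_rest:
                if hyp_items[hj][0] == want:
                    v = rect_iou(gt_items[gi][1], hyp_items[hj][1])
                    if v >= threshold:
                        matched.append((gi, hj, v))
                        gt_rest.remove(gi)
                        hyp_rest.remove(hj)
                    break
        extra = _best_injection(
            [gt_items[i] for i in gt_rest], [hyp_items[j] for j in hyp_rest], threshold
        )
        for a, b, v in extra:
            matched.append((gt_rest[a], hyp_rest[b], v))
        used_g = {m[0] for m in matched}
        used_h = {m[1] for m in matched}
        fn += len(gt_items) - len(matched)
        fp += len(hyp_items) - len(matched)
        new_prev = {}
        for gi, hj, v in matched:
            g_id, h_id = gt_items[gi][0], hyp_items[hj][0]
            if g_id in last_match and last_match[g_id] != h_id:
                ids += 1
            last_match[g_id] = h_id
            new_prev[g_id] = h_id
            overlap_sum += v
            n_matches += 1
        prev_pair = new_prev
    mota = (1.0 - (fn + fp + ids) / gt_total) * 100.0 if gt_total else None
    motp = overlap_sum / n_matches * 100.0 if n_matches else None
    return {"mota": mota, "motp": motp, "ids": ids, "fp": fp, "fn": fn,
            "gt": gt_total}
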