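"""Independent brute-force oracles used only by the tests."""

from itertools import product


def dollo_min_losses(tree, tip_states) -> int:
    """Minimum present->absent edge count over all irreversible labelings.

    Enumerates every assignment of present/absent to internal nodes (tips
    fixed), discards assignments with an absent parent above a present child,
    and returns the minimum number of present->absent edges.  Exponential in
    the internal node count — only for tiny trees.
    """
    internals = [n for n in tree.preorder() if not tree.is_tip(n)]
    tips = tree.tip_labels
    best = None
    for bits in product([True, False], repeat=len(internals)):
        state = dict(zip(internals, bits))
        for t in tips:
            state[t] = tip_states[t] == "present"
        ok = True
        losses = 0
        for node in tree.preorder():
            parent = tree.parent(node)
            if parent is None:
                continue
            if not state[parent] and state[node]:
                ok = False
                break
            if state[parent] and not state[node]:
                losses += 1
        if ok and (best is None or losses < best):
            best = losses
    return best


def random_tree_and_states(rng, n_tips=None):
    """A random small taxonomy with random binary tip states."""
    from torcscan import SimConfig, simulate_taxonomy

    n = int(n_tips if n_tips is not None else rng.integers(3, 11))
    cfg = SimConfig(
        n_tips=n,
        n_clades=int(rng.integers(1, min(3, n // 2) + 1)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    tree = simulate_taxonomy(cfg)
    states = {
        t: "present" if rng.random() < 0.5 else "absent" for t in tree.tip_labels
    }
    return tree, states
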