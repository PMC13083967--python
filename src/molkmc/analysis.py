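"""Post-hoc analyses of reaction-emulation runs.

Shift classification ("1-n" labels for intramolecular hydrogen transfers),
selection probabilities across runs, rate convergence versus number of
barrier predictions, radical migration distances, and quantum-yield
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptySelectionError
from .topology import Topology, find_radicals, graph_distance

#: Default upper bound for explicit "1-n" labels: transfers spanning more
#: than this many bonds within one molecule are "long-range".
DEFAULT_MAX_BONDS = 6


def classify_shift(
    t: Topology, acceptor: int, donor_heavy: int, max_bonds: int = DEFAULT_MAX_BONDS
) -> str:
    """Label a hydrogen transfer by the positions of radical and donor.

    Counting includes both endpoint heavy atoms, so a bond-graph distance of
    k gives the label "1-(k+1)": the 1-5 shift (distance 4) proceeds through
    the favourable six-membered-ring transition state. Atoms in different
    molecules give "intermolecular"; same-molecule transfers spanning more
    than ``max_bonds`` bonds give "long-range".
    """
    dist = graph_distance(t, acceptor, donor_heavy)
    if dist is None:
        return "intermolecular"
    if dist > max_bonds:
        return "long-range"
    return f"1-{dist + 1}"


def _iter_records(records) -> Iterable:
    for item in records:
        if isinstance(item, (list, tuple)):
            yield from item
        else:
            yield item


def selection_probabilities(
    records, considered: Sequence[str]
) -> dict[str, float]:
    """Normalised selection counts per shift label over runs.

    Labels outside ``considered`` are dropped before normalising (mirroring
    comparisons where experimentally invisible shifts are set to zero).
    ``records`` may be RunRecords or nested lists of them.
    """
    considered = list(considered)
    counts = {label: 0 for label in considered}
    total = 0
    for rec in _iter_records(records):
        label = getattr(rec.chosen, "label", None)
        if label in counts:
            counts[label] += 1
            total += 1
    if total == 0:
        raise EmptySelectionError(
            f"no chosen events with labels in {considered}"
        )
    return {label: counts[label] / total for label in considered}


def rate_convergence(
    rates: Sequence[float], block_sizes: Sequence[int]
) -> dict[int, float]:
    """Running mean rate over the first k predictions, for each requested k."""
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        raise EmptySelectionError("no rates")
    out: dict[int, float] = {}
    for k in block_sizes:
        if not (1 <= k <= arr.size):
            raise ValueError(f"block size {k} out of range 1..{arr.size}")
        out[int(k)] = float(np.mean(arr[:k]))
    return out


def migration_distance(
    states: Sequence[tuple[Topology, object]], origin_atoms: Sequence[int]
) -> list[np.ndarray]:
    """Distance of every current radical to its nearest origin atom, per step.

    ``states`` are the per-step (topology, frame) product states of a run;
    ``origin_atoms`` typically the two atoms of the homolytically cleaved
    bond. Distances are Euclidean (Å) and invariant under rigid-body motion
    of the whole frame.
    """
    origins = list(origin_atoms)
    out: list[np.ndarray] = []
    for topo, frame in states:
        for o in origins:
            topo.check_index(o)
        pos = np.asarray(frame.positions, dtype=float)
        radicals = sorted(find_radicals(topo).members)
        if radicals:
            d = np.linalg.norm(
                pos[radicals][:, None, :] - pos[origins][None, :, :], axis=-1
            )
            out.append(d.min(axis=1))
        else:
            out.append(np.empty(0))
    return out


@dataclass
class YieldSummary:
    mean: float
    sd: float
    n: int
    single_sample: bool = False


def yield_summary(yields: Sequence[float]) -> YieldSummary:
    """Mean ± sample standard deviation (n-1) of per-ensemble quantum yields.

    A single value returns sd = 0 by convention, flagged via
    ``single_sample``.
    """
    arr = np.asarray(list(yields), dtype=float)
    if arr.size == 0:
        raise EmptySelectionError("no yields")
    if arr.size == 1:
        return YieldSummary(mean=float(arr[0]), sd=0.0, n=1, single_sample=True)
    return YieldSummary(
        mean=float(np.mean(arr)), sd=float(np.std(arr, ddof=1)), n=int(arr.size)
    )


# ---------------------------------------------------------------------------
# Tabular output and optional plots
# ---------------------------------------------------------------------------


def probabilities_to_tsv(probs: Mapping[str, float], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"label": list(probs), "probability": list(probs.values())}
    ).to_csv(path, sep="\t", index=False)


def convergence_to_tsv(means: Mapping[int, float], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"n_predictions": list(means), "mean_rate": list(means.values())}
    ).to_csv(path, sep="\t", index=False)


def plot_selection_probabilities(probs: Mapping[str, float], path) -> None:
    """Bar chart of shift-selection probabilities."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(list(probs), list(probs.values()), color="#4878d0")
    ax.set_ylabel("selection probability")
    ax.set_xlabel("hydrogen shift")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rate_convergence(means: Mapping[int, float], path) -> None:
    """Mean rate versus number of barrier predictions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ks = sorted(means)
    ax.plot(ks, [means[k] for k in ks], marker="o")
    ax.set_xlabel("number of rate predictions")
    ax.set_ylabel("mean rate (s$^{-1}$)")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
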