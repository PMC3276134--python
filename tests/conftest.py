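import numpy as np
import pytest

from senescreen.plate_model import CultureSeries, ScreenDataset, WellPosition


def make_dataset(series: dict[str, list[list[float]]], scale="transformed",
                 design="solid") -> ScreenDataset:
    """Build a small dataset from {genotype: [replicate size lists]}."""
    cultures = []
    P = None
    for gi, (genotype, reps) in enumerate(sorted(series.items())):
        for ri, sizes in enumerate(reps):
            P = len(sizes)
            cultures.append(
                CultureSeries(
                    position=WellPosition("T01", gi + 1, ri + 1),
                    genotype=genotype,
                    sizes=np.asarray(sizes, dtype=float),
                )
            )
    return ScreenDataset(cultures=cultures, passage_count=P, scale=scale, design=design)


@pytest.fixture(scope="session")
def archetype_screen():
    """The canonical three-class synthetic screen (40 genotypes per class,
    8 replicates, seeded) with its transformed dataset, MDPs and truth."""
    from senescreen import (
        archetype_scenario,
        compute_all_mdps,
        load_scenario,
        simulate_screen,
        transform_sizes,
    )

    layouts, cfg, noise = load_scenario(archetype_scenario(seed=1))
    raw, truth = simulate_screen(layouts, cfg, noise)
    dataset = transform_sizes(raw)
    mdps = compute_all_mdps(dataset)
    return {"raw": raw, "dataset": dataset, "mdps": mdps, "truth": truth}
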