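import numpy as np
import pytest

from minikaryo.model import (
    GeneFeature,
    Karyotype,
    Minichromosome,
    Orientation,
    Status,
    canonical_vocabulary,
    load_fixture,
)

TOY = dict(ncr_len_range=(250, 330), length_scale=0.12)
TOY_READS = dict(coverage=30, read_len=100, insert_len=180)
TOY_ASM = dict(min_overlap=50, min_identity=0.99)


@pytest.fixture(scope="session")
def vituli():
    return load_fixture("L_vituli")


@pytest.fixture(scope="session")
def africanus():
    return load_fixture("L_africanus")


@pytest.fixture(scope="session")
def mrca_anoplura():
    return load_fixture("MRCA_Anoplura")


@pytest.fixture(scope="session")
def mrca_linognathus():
    return load_fixture("MRCA_Linognathus")


def random_karyotype(rng: np.random.Generator, n_chrom: int = 6, decorate: bool = True) -> Karyotype:
    """Random valid karyotype: vocabulary partition with optional extras."""
    names = [name for name, _ in canonical_vocabulary()]
    rng.shuffle(names)
    cuts = sorted(rng.choice(np.arange(1, len(names)), size=n_chrom - 1, replace=False))
    parts = np.split(np.array(names), cuts)
    minis = []
    for part in parts:
        genes = []
        for name in part:
            orientation = (
                Orientation.reverse
                if decorate and rng.random() < 0.1
                else Orientation.forward
            )
            genes.append(GeneFeature(name=str(name), orientation=orientation))
        if decorate and rng.random() < 0.3:
            donor = str(names[int(rng.integers(len(names)))])
            status = Status.pseudo if rng.random() < 0.5 else Status.full
            copy = 2 if status is Status.full else 1
            genes.insert(
                int(rng.integers(len(genes) + 1)),
                GeneFeature(name=donor, status=status, copy=copy),
            )
        sizes = {}
        if decorate and rng.random() < 0.5:
            c, n = int(rng.integers(500, 2000)), int(rng.integers(500, 1500))
            sizes = dict(cluster_len_bp=c, ncr_len_bp=n, total_len_bp=c + n)
        minis.append(Minichromosome(genes=genes, **sizes))
    labels = [m.label for m in minis]
    if len(set(labels)) != len(labels):  # rare duplicate-label collision
        return random_karyotype(rng, n_chrom, decorate)
    return Karyotype(species="random", minichromosomes=minis)


def partition_karyotype(rng: np.random.Generator, universe: list[str], n_chrom: int) -> Karyotype:
    """Plain partition karyotype (no pseudos/duplicates) over a gene subset."""
    names = list(universe)
    rng.shuffle(names)
    cuts = sorted(rng.choice(np.arange(1, len(names)), size=n_chrom - 1, replace=False))
    parts = np.split(np.array(names), cuts)
    minis = [
        Minichromosome(genes=[GeneFeature(name=str(n)) for n in part]) for part in parts
    ]
    return Karyotype(species="partition", minichromosomes=minis)
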