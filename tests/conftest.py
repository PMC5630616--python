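import numpy as np
import pytest

from prefnet.network_core import (
    NetworkGroup,
    SpeciesRegistry,
    WeightedNetwork,
)


def make_group(site_counts, group_id="g", registry=None, **meta):
    """Build a NetworkGroup from {site_id: {(host, par): count}}."""
    if registry is None:
        hosts, pars = [], []
        for counts in site_counts.values():
            for (h, p) in counts:
                if h not in hosts:
                    hosts.append(h)
                if p not in pars:
                    pars.append(p)
        registry = SpeciesRegistry.from_lists(hosts, pars)
    networks = [WeightedNetwork(s, dict(c)) for s, c in site_counts.items()]
    return NetworkGroup(group_id=group_id, registry=registry, networks=networks, **meta)


@pytest.fixture
def two_host_group():
    """Two hosts, one parasitoid, two sites with counts {2, 4} at each site."""
    return make_group(
        {
            "s1": {("hA", "p1"): 2, ("hB", "p1"): 4},
            "s2": {("hA", "p1"): 2, ("hB", "p1"): 4},
        }
    )


@pytest.fixture
def dense_group():
    """A 3x3 dense two-site group with fixed pseudo-random counts."""
    rng = np.random.default_rng(42)
    hosts = ["h1", "h2", "h3"]
    pars = ["p1", "p2", "p3"]
    sites = {}
    for s in ("s1", "s2"):
        sites[s] = {
            (h, p): int(rng.integers(1, 30)) for h in hosts for p in pars
        }
    return make_group(sites)


def random_group(rng, n_hosts=4, n_pars=3, n_sites=3, max_count=20, p_zero_marker=0.1):
    """A randomized group for property tests, with occasional zero markers."""
    hosts = [f"h{i}" for i in range(n_hosts)]
    pars = [f"p{j}" for j in range(n_pars)]
    sites = {}
    for k in range(n_sites):
        counts = {}
        for h in hosts:
            for p in pars:
                u = rng.random()
                if u < 0.4:
                    counts[(h, p)] = int(rng.integers(1, max_count))
                elif u < 0.4 + p_zero_marker:
                    counts[(h, p)] = 0
        sites[f"s{k}"] = counts
    # guarantee at least one positive count overall
    sites["s0"][(hosts[0], pars[0])] = 5
    return make_group(sites, registry=SpeciesRegistry.from_lists(hosts, pars))
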