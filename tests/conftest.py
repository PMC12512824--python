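"""Shared fixtures: the scripted rearrangement suite, simulated once."""

import time
from dataclasses import dataclass

import pytest

from svblocks import formats_io
from svblocks.model import structure_summary
from svblocks.pipeline import RunConfig, run_extract
from svblocks.simulate import category_suite, simulate


@dataclass
class Scenario:
    name: str
    sim: object  # SimResult
    cfg: RunConfig
    json_path: str
    doc: object  # JsonDocument
    seconds: float  # simulate + extract wall time


@pytest.fixture(scope="session")
def suite(tmp_path_factory):
    """Every scripted category, simulated and reconstructed once per session."""
    root = tmp_path_factory.mktemp("suite")
    scenarios = {}
    for name, spec in category_suite(base_seed=1):
        t0 = time.time()
        sim = simulate(spec, root / "sim")
        cfg = RunConfig(bam=sim.bam_path, vcf=sim.vcf_path, sample_id=name,
                        out_dir=str(root / name))
        json_path, _ = run_extract(cfg)
        doc = formats_io.read_json(json_path)
        scenarios[name] = Scenario(
            name=name, sim=sim, cfg=cfg, json_path=json_path, doc=doc,
            seconds=time.time() - t0,
        )
    return scenarios


def single_event(scenario):
    assert len(scenario.doc.events) == 1, (
        f"{scenario.name}: expected one reconstructed event, "
        f"got {len(scenario.doc.events)}"
    )
    return scenario.doc.events[0]


def summaries(scenario):
    return (structure_summary(single_event(scenario)),
            structure_summary(scenario.sim.truth))
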