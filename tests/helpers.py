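"""Shared helpers for driving the consensus pipeline on simulated studies."""

from dualbind.consensus import consensus_two_reps, extend_summits, merge_close_summits


def build_consensus(study, factor):
    reps = []
    for rep in (0, 1):
        ext = extend_summits(study.chip.summits[factor][rep])
        reps.append(merge_close_summits(ext))
    cons, _ = consensus_two_reps(
        reps[0], reps[1], study.chip.narrows[factor][0], study.chip.narrows[factor][1]
    )
    return cons


def consensus_site_names(cons):
    return {n for r in cons if r.name for n in r.name.split(",")}
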