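"""Synthetic-data generators: reproducibility, realism of the generated
structure, and loop closure with the consuming modules."""

import numpy as np
import pytest

from lakeredox.gene_mapping import DEFAULT_GENE_PROCESS_MAP, mae, modeled_gene_proxy
from lakeredox.synthetic import (
    default_scenario,
    make_community,
    make_gene_tables,
    make_observations,
    make_scenario,
)


class TestMakeScenario:
    def test_seeded_reproducibility(self):
        t1, r1 = make_scenario(seed=4, t_end=30, save_every=30)
        t2, r2 = make_scenario(seed=4, t_end=30, save_every=30)
        assert t1.true_parameters == t2.true_parameters
        for sp in r1.conc:
            assert np.array_equal(r1.conc[sp], r2.conc[sp])

    def test_redox_zonation(self, baseline_result):
        res = baseline_result
        final = {sp: res.conc[sp][:, -1] for sp in res.conc}
        assert np.argmax(final["O2"]) == 0
        for sp in ("Fe2+", "HS-", "CH4"):
            assert np.argmax(final[sp]) == res.grid.n_cells - 1

    def test_no_reactions_reduces_to_transport(self):
        zeroed = {  # all rate constants off
            lbl: 0.0
            for lbl in default_scenario().network.process_labels
        }
        sc = default_scenario(rate_constants=zeroed, t_end=30, save_every=30)
        res = sc.run()
        for field in res.rates.values():
            assert np.all(field == 0.0)
        # sulfate has no source/sink or boundary: profile unchanged
        assert res.conc["SO42-"][:, -1] == pytest.approx(np.full(23, 60.0), rel=1e-5)


class TestMakeObservations:
    def test_zero_noise_reproduces_model(self, baseline_result):
        obs = make_observations(baseline_result, noise_sd=0.0, seed=0)
        for o in obs:
            ti = int(np.argmin(np.abs(baseline_result.times - o.time)))
            expected = np.interp(
                o.depths,
                baseline_result.grid.depths,
                baseline_result.conc[o.species][:, ti],
            )
            assert o.values == pytest.approx(expected)

    def test_lognormal_noise_centred_on_model(self, baseline_result):
        # median of many realisations ~ model value (lognormal, mu=0)
        reps = [
            make_observations(
                baseline_result, noise_sd=0.3, seed=s, species=("SO42-",)
            )[0].values
            for s in range(300)
        ]
        noise_free = make_observations(
            baseline_result, noise_sd=0.0, seed=0, species=("SO42-",)
        )[0].values
        med = np.median(reps, axis=0)
        assert med == pytest.approx(noise_free, rel=0.1)

    def test_seeded_reproducibility(self, baseline_result):
        a = make_observations(baseline_result, noise_sd=0.2, seed=5)
        b = make_observations(baseline_result, noise_sd=0.2, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)


class TestMakeGeneTables:
    def test_zero_noise_closes_loop_with_proxy(self, baseline_result):
        tables = make_gene_tables(baseline_result, noise_sd=0.0, seed=0)
        for gp in tables:
            proxy = modeled_gene_proxy(
                baseline_result,
                DEFAULT_GENE_PROCESS_MAP,
                gp.gene_set,
                gp.sample_depths,
                float(baseline_result.times[-1]),
            )
            assert mae(gp.values, proxy.values) == pytest.approx(0.0, abs=1e-12)

    def test_noise_increases_expected_mae(self, baseline_result):
        def mean_mae(sd):
            vals = []
            for s in range(40):
                tables = make_gene_tables(baseline_result, noise_sd=sd, seed=s)
                gp = next(t for t in tables if t.gene_set == "dsrAB")
                proxy = modeled_gene_proxy(
                    baseline_result, DEFAULT_GENE_PROCESS_MAP, "dsrAB",
                    gp.sample_depths, float(baseline_result.times[-1]),
                )
                vals.append(mae(gp.values, proxy.values))
            return np.mean(vals)

        assert mean_mae(0.05) < mean_mae(0.2) < mean_mae(0.6)


class TestMakeCommunity:
    def test_seeded_reproducibility(self):
        a = make_community(seed=2)
        b = make_community(seed=2)
        assert a.otu_amplicon.table.equals(b.otu_amplicon.table)
        assert a.otu_metagenomic.table.equals(b.otu_metagenomic.table)
        assert [c.coverage for c in a.contigs] == [c.coverage for c in b.contigs]
        assert a.planted_pairs == b.planted_pairs

    def test_shapes_and_controls(self, community):
        assert community.otu_amplicon.table.shape == (62, 11)
        assert len(community.planted_pairs) == 12
        assert len(community.control_pairs) == 8
        assert set(community.control_pairs) <= set(community.planted_pairs)
        for _, mag in community.planted_pairs:
            n_contigs = sum(1 for c in community.contigs if c.bin_id == mag)
            assert 3 <= n_contigs <= 10

    def test_tables_pass_validators(self, tmp_path, community):
        from lakeredox import io as lio
        from lakeredox.validate import validate_inputs

        lio.write_abundance_tsv(community.otu_amplicon, tmp_path / "amp.tsv")
        lio.write_abundance_tsv(community.otu_metagenomic, tmp_path / "met.tsv")
        lio.write_contigs_tsv(community.contigs, tmp_path / "contigs.tsv")
        lio.write_taxonomy_tsv(
            list(community.taxonomies.values()), tmp_path / "tax.tsv"
        )
        report = validate_inputs(
            {
                "otu_amplicon": tmp_path / "amp.tsv",
                "otu_metagenomic": tmp_path / "met.tsv",
                "contigs": tmp_path / "contigs.tsv",
                "taxonomy": tmp_path / "tax.tsv",
            }
        )
        assert report == []

    def test_noise_free_community_separates_cleanly(self):
        from lakeredox.community import (
            AbundanceMatrix,
            bin_abundance_table,
            combined_distance,
            dual_l1_normalize,
            taxonomy_fraction,
            match,
            train_tolerance,
        )

        # dual-L1 normalisation divides sample columns by different
        # totals in the OTU vs the MAG table, so even exactly co-varying
        # pairs keep a small residual distance; train on all controls
        # and assert clean separation from partner-less OTUs
        comm = make_community(seed=9, noise_sd=0.0, n_controls=12)
        amp = dual_l1_normalize(comm.otu_amplicon)
        met = dual_l1_normalize(comm.otu_metagenomic)
        mags = dual_l1_normalize(
            AbundanceMatrix(
                table=bin_abundance_table(
                    comm.contigs, comm.sample_ids, comm.library_reads
                )
            )
        )
        ta, tm = [], []
        for otu, mag in comm.control_pairs:
            f = taxonomy_fraction(comm.taxonomies[otu], comm.taxonomies[mag])
            ta.append(combined_distance(amp.row(otu), mags.row(mag), f))
            tm.append(combined_distance(met.row(otu), mags.row(mag), f))
        cands = match(
            amp, met, mags, comm.taxonomies, train_tolerance(ta), train_tolerance(tm)
        )
        accepted = {(c.otu_id, c.mag_id) for c in cands if c.accepted}
        planted = set(comm.planted_pairs)
        # only multinomial sampling noise remains in the amplicon channel
        assert len(accepted & planted) == len(planted)
        assert len(accepted - planted) == 0
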