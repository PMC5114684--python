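import json

import pytest

import mirsponge as ms


@pytest.fixture(scope="module")
def planted_screen(params):
    """2-MBS sponge for a planted miRNA screened against 60 random ones."""
    planted = "GUCCAGUUUUCCCAGGAAUCCCU"
    mirnas = ms.generate_synthetic_mirna_set(60, (19, 25), 0.5, seed=1,
                                             planted=[planted])
    construct = ms.build_construct(
        ms.perfect_mbs(mirnas[-1]), repeats=2, spacer="AATT"
    )
    report = ms.screen_construct(construct, mirnas, ms.ScreenConfig(params=params))
    return mirnas, construct, report


class TestSeedMatch:
    def _site(self, target, query, params, limits):
        return ms.hybridize_mfe(ms.rna(target), query, params, limits)

    def test_perfect_site_passes_six_mer(self, params, limits, mir145):
        target = ms.perfect_mbs(mir145).mbs_dna.as_rna()
        site = self._site(str(target), mir145, params, limits)
        assert ms.seed_match(site, mir145, ms.SeedMode.SIX_MER, target=target)

    def test_wobble_in_seed_fails(self, params, limits):
        # miRNA position 4 is G paired to target U (wobble) in a full duplex
        query = ms.MiRNARecord("x-miR-w", ms.rna("CCCGCCCCCCCCCCCC"))
        target = ms.rna("GGGGGGGGGGGGUGGG")  # U faces the seed G
        site = self._site(str(target), query, params, limits)
        assert site is not None
        assert ms.seed_match(site, query, ms.SeedMode.NONE, target=target)
        assert not ms.seed_match(site, query, ms.SeedMode.SIX_MER, target=target)
        assert ms.seed_match(site, query, ms.SeedMode.SIX_MER,
                             allow_wobble=True, target=target)

    def test_none_mode_always_true(self, params, limits, mir145):
        target = ms.rna(str(ms.perfect_mbs(mir145).mbs_dna.as_rna()))
        site = self._site(str(target), mir145, params, limits)
        assert ms.seed_match(site, mir145, ms.SeedMode.NONE)

    def test_loop_inside_seed_fails(self, params, limits, mir145):
        # bulge the sponge opposite seed positions 2-5 instead of 10-13
        spec = ms.bulged_mbs(mir145, (3, 6))
        target = spec.mbs_dna.as_rna()
        site = self._site(str(target), mir145, params, limits)
        assert site is not None
        assert not ms.seed_match(site, mir145, ms.SeedMode.SIX_MER, target=target)


class TestScreenConstruct:
    def test_planted_ranks_first_with_two_sites(self, planted_screen):
        _, _, report = planted_screen
        assert report.hits, "planted miRNA must be reported"
        top = report.hits[0]
        assert top.mirna.name == "planted-0001"
        assert len(top.sites) == 2
        assert top.total_energy == pytest.approx(
            sum(s.energy for s in top.sites), abs=1e-9
        )

    def test_empty_set_gives_empty_report(self, params, mir145):
        construct = ms.build_construct(ms.perfect_mbs(mir145), repeats=2)
        report = ms.screen_construct(construct, [], ms.ScreenConfig(params=params))
        assert report.hits == ()

    def test_cutoff_excludes_weak_binders(self, params, limits, mir145):
        construct = ms.build_construct(ms.bulged_mbs(mir145), repeats=1)
        best = ms.hybridize_mfe(construct.transcript, mir145, params, limits)
        config = ms.ScreenConfig(cutoff=best.energy - 1.0, params=params)
        report = ms.screen_construct(construct, [mir145], config)
        assert report.hits == ()

    def test_order_invariance(self, planted_screen, params):
        mirnas, construct, report = planted_screen
        reversed_report = ms.screen_construct(
            construct, list(reversed(mirnas)), ms.ScreenConfig(params=params)
        )
        key = [(h.mirna.name, h.total_energy, tuple(s.target_interval for s in h.sites))
               for h in report.hits]
        rkey = [(h.mirna.name, h.total_energy, tuple(s.target_interval for s in h.sites))
                for h in reversed_report.hits]
        assert key == rkey

    def test_total_energy_additivity(self, planted_screen, params, limits):
        _, construct, report = planted_screen
        top = report.hits[0]
        independent = sum(
            ms.duplex_energy_of_pairing(
                construct.transcript, top.mirna.sequence, s.pairing, params
            )
            for s in top.sites
        )
        assert top.total_energy == pytest.approx(independent, abs=1e-9)

    def test_seed_filter_monotone(self, planted_screen, params):
        mirnas, construct, _ = planted_screen
        names = {}
        for mode in (ms.SeedMode.NONE, ms.SeedMode.OFFSET_SIX_MER,
                     ms.SeedMode.SIX_MER, ms.SeedMode.SEVEN_MER):
            config = ms.ScreenConfig(cutoff=-15.0, seed_mode=mode, params=params)
            report = ms.screen_construct(construct, mirnas, config)
            names[mode] = {h.mirna.name for h in report.hits}
        assert names[ms.SeedMode.SEVEN_MER] <= names[ms.SeedMode.SIX_MER]
        assert names[ms.SeedMode.SIX_MER] <= names[ms.SeedMode.NONE]
        assert names[ms.SeedMode.SEVEN_MER] <= names[ms.SeedMode.OFFSET_SIX_MER]
        assert names[ms.SeedMode.OFFSET_SIX_MER] <= names[ms.SeedMode.NONE]


class TestRankHits:
    def _hit(self, name, energies, params, limits):
        rec = ms.MiRNARecord(name, ms.rna("GUCCAGUUUUCCCAGGAAUCCCU"))
        target = ms.perfect_mbs(rec).mbs_dna.as_rna()
        site = ms.hybridize_mfe(target, rec, params, limits)
        sites = tuple(
            ms.DuplexSite(site.target_interval, site.pairing, e, name)
            for e in energies
        )
        return ms.MiRNAHit(rec, sites, sum(energies))

    def test_ascending_order(self, params, limits):
        a = self._hit("a-miR-1", [-50.0], params, limits)
        b = self._hit("b-miR-1", [-69.5], params, limits)
        assert [h.mirna.name for h in ms.rank_hits([a, b])] == ["b-miR-1", "a-miR-1"]

    def test_ties_alphabetical(self, params, limits):
        a = self._hit("b-miR-2", [-30.0], params, limits)
        b = self._hit("a-miR-9", [-30.0], params, limits)
        assert [h.mirna.name for h in ms.rank_hits([a, b])] == ["a-miR-9", "b-miR-2"]

    def test_empty(self):
        assert ms.rank_hits([]) == []


class TestReportFormats:
    def test_tsv_json_text_agree(self, planted_screen):
        _, _, report = planted_screen
        tsv = ms.report_to_tsv(report)
        payload = json.loads(ms.report_to_json(report))
        text = ms.report_to_text(report)
        first = tsv.splitlines()[1].split("\t")
        assert first[0] == payload["hits"][0]["mirna"]
        assert float(first[3]) == pytest.approx(
            payload["hits"][0]["total_energy"], abs=0.005
        )
        assert f"{payload['hits'][0]['total_energy']:.1f}" in text

    def test_json_echoes_config(self, planted_screen):
        _, _, report = planted_screen
        payload = json.loads(ms.report_to_json(report))
        assert payload["config"]["cutoff"] == -25.0
        assert payload["config"]["seed_mode"] == "6mer"
        assert payload["set_provenance"]["records"] == 61
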