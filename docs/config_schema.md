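# XML configuration schema

A single document configures both the parameter set and the scenario.  All
elements and attributes are optional unless marked **required**; any value
left out is filled from the default registry and the substitution is logged
(and recorded in `ParameterSet.substituted_defaults`).

Units: micrometre (um), hour (h), g/L, picogram (pg), g/um^3.

```xml
<granulesim name="my-experiment">

  <!-- square domain; side must be an integer multiple of spacing -->
  <domain side="508.0" spacing="4.0" maxGranuleDiameter="500.0" slab="4.0"/>

  <!-- gamma: relative diffusivity applied at biomass-occupied nodes -->
  <solutes gamma="0.5">
    <!-- name (required): cellobiose | oleate | lactate | acetate |
         ethanol | hydrogen | methane -->
    <solute name="cellobiose" diffusivity="4.0e5" bulk="1.5"/>
  </solutes>

  <!-- name (required): clostridium1 | clostridium2 | oleate_degrader |
       desulfovibrio | methanogen1 | methanogen2.
       KiSubstrate: Haldane self-inhibition constant (omit for Monod).
       KiProduct: acetate product-inhibition constant (omit for none). -->
  <species name="desulfovibrio" muMax="0.06" Ks="0.03"
           KiSubstrate="5.0" KiProduct="1.5" alphaB="0.10"
           deathThreshold="1e-4" deathDuration="120"
           divisionRadius="4.0" birthFraction="0.7937" density="1.5e-13"/>

  <solver tol="1e-6" maxOuter="200" relax="0.7" capFactor="10"/>

  <simulation dt="0.5" duration="1008" randomSeed="1" snapshotEvery="24"/>

  <!-- timed introduction of a guild (bioaugmentation).
       species, time: required.  Without <site> children, four seed sites
       are auto-placed at the corners of the square just enclosing the
       granule at event time.  @z is accepted and ignored (2-D model). -->
  <event time="408" species="oleate_degrader" cellsPerSite="1" biomass="20">
    <site x="76.0" y="76.0" z="0"/>
  </event>

  <!-- step change of a bulk feed concentration (all three required) -->
  <feed solute="oleate" time="408" bulk="1.5"/>
  <feed solute="cellobiose" time="408" bulk="0.0"/>

  <!-- initial inoculum at the domain centre -->
  <inoculum guilds="clostridium1,clostridium2,desulfovibrio,methanogen1,methanogen2"
            cells="40" radius="40.0" biomass="20.0"/>

</granulesim>
```

`granulesim.parameters.load_parameters` reads the parameter elements;
`granulesim.engine.scenario_from_config` reads the full document including
`<simulation>`, `<event>`, `<feed>` and `<inoculum>`.
`granulesim.parameters.to_xml` writes a parameter document that reloads
bit-identically.
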