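<?xml version='1.0' encoding='UTF-8'?>
<ParameterSet Name="Synthetic-HCNOSP" Kappa="0.5337643497742726" Provenance="Synthetic element-granularity set covering H/C/N/O/S/P; generated, not fitted to any QM reference.">
  <Element Symbol="C">
    <Parameters A="6.943020663097078" B="8.37808189408237"/>
  </Element>
  <Element Symbol="H">
    <Parameters A="2.959946870025822" B="10.687548118721818"/>
  </Element>
  <Element Symbol="N">
    <Parameters A="6.109397129277813" B="9.711073282447863"/>
  </Element>
  <Element Symbol="O">
    <Parameters A="7.348144579234323" B="10.518986096238065"/>
  </Element>
  <Element Symbol="P">
    <Parameters A="2.6557775626360165" B="8.764399369111356"/>
  </Element>
  <Element Symbol="S">
    <Parameters A="7.959151949653355" B="7.940172480519251"/>
  </Element>
</ParameterSet>
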