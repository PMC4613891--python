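<?xml version='1.0' encoding='UTF-8'?>
<ParameterSet Name="Synthetic-HCNO" Kappa="0.5919530443898682" Provenance="Synthetic element-granularity set for H/C/N/O point-cloud molecules; generated, not fitted to any QM reference.">
  <Element Symbol="C">
    <Parameters A="6.708832471819862" B="10.730225481835294"/>
  </Element>
  <Element Symbol="H">
    <Parameters A="7.661195033663324" B="8.875368266732586"/>
  </Element>
  <Element Symbol="N">
    <Parameters A="3.765971367181569" B="13.381805491383314"/>
  </Element>
  <Element Symbol="O">
    <Parameters A="7.215989268071416" B="8.913107410324184"/>
  </Element>
</ParameterSet>
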