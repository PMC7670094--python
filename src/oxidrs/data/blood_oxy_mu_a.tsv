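# fully oxygen-saturated whole blood, 145 g Hb/L (1/mm)
# SYNTHETIC approximation; substitute your own table for exact literature curves.
# wavelength_nm	mu_a_per_mm
450	32.5158
452	27.5504
454	23.0062
456	19.0714
458	15.9346
460	13.7841
462	12.2925
464	11.0202
466	9.98726
468	9.21385
470	8.72009
472	8.38889
474	8.10129
476	7.87451
478	7.72579
480	7.67239
482	7.72974
484	7.883
486	8.10397
488	8.36444
490	8.63623
492	8.95324
494	9.35356
496	9.81527
498	10.3164
500	10.8351
502	11.4178
504	12.0863
506	12.7817
508	13.4451
510	14.0176
512	14.4693
514	14.8484
516	15.2124
518	15.6192
520	16.1264
522	16.7939
524	17.6193
526	18.5665
528	19.5996
530	20.6826
532	22.0915
534	23.869
536	25.6295
538	26.9873
540	27.5568
542	27.5858
544	27.2159
546	26.7567
548	26.3751
550	25.8279
552	24.5779
554	22.7208
556	20.7133
558	18.1867
560	16.8853
562	16.9646
564	17.1854
566	17.8743
568	20.3612
570	23.0327
572	25.4394
574	27.7296
576	28.7495
578	27.8503
580	25.9356
582	22.8371
584	18.6349
586	13.7691
588	10.1519
590	7.45395
592	5.55581
594	4.04644
596	2.95052
598	2.15838
600	1.65643
602	1.38688
604	1.17341
606	1.00702
608	0.878731
610	0.779559
612	0.70005
614	0.634485
616	0.57948
618	0.531651
620	0.487613
622	0.445742
624	0.407051
626	0.372111
628	0.341489
630	0.315758
632	0.293633
634	0.273622
636	0.255978
638	0.240951
640	0.228795
642	0.21898
644	0.210583
646	0.203262
648	0.196678
650	0.19049
652	0.18434
654	0.17835
656	0.172899
658	0.168365
660	0.165126
662	0.162708
664	0.160409
666	0.158259
668	0.156291
670	0.154538
672	0.153031
674	0.151803
676	0.150886
678	0.150313
680	0.150114
682	0.150114
684	0.150114
686	0.150114
688	0.150114
690	0.150114
692	0.150114
694	0.150114
696	0.150114
698	0.150114
700	0.150114
702	0.150458
704	0.151436
706	0.152974
708	0.154992
710	0.157414
712	0.160164
714	0.163163
716	0.166335
718	0.169603
720	0.17289
722	0.176567
724	0.180989
726	0.186053
728	0.191657
730	0.197698
732	0.204073
734	0.21068
736	0.217416
738	0.224179
740	0.230865
742	0.237841
744	0.245346
746	0.25309
748	0.260783
750	0.268135
752	0.275202
754	0.282229
756	0.289211
758	0.296142
760	0.303018
762	0.309832
764	0.31658
766	0.323256
768	0.329854
770	0.33637
772	0.342798
774	0.349132
776	0.355368
778	0.361499
780	0.367521
782	0.373415
784	0.379176
786	0.384821
788	0.390364
790	0.395822
792	0.401211
794	0.406547
796	0.411845
798	0.417121
800	0.42239
802	0.427694
804	0.433051
806	0.438454
808	0.443891
810	0.449351
812	0.454825
814	0.460302
816	0.465773
818	0.471225
820	0.47665
822	0.482037
824	0.487375
826	0.492654
828	0.497865
830	0.502995
832	0.508036
834	0.512977
836	0.517807
838	0.522517
840	0.527095
842	0.531532
844	0.535817
846	0.53994
848	0.543891
850	0.547658
852	0.551311
854	0.554921
856	0.558487
858	0.562006
860	0.565474
862	0.568889
864	0.572249
866	0.57555
868	0.57879
870	0.581967
872	0.585077
874	0.588118
876	0.591087
878	0.593981
880	0.596799
882	0.599536
884	0.602191
886	0.60476
888	0.607241
890	0.609632
892	0.611929
894	0.614129
896	0.616231
898	0.618231
900	0.620127
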